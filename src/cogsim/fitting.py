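"""Statsmodels-style model objects for fitting constitutive laws to curves.

Two small model classes turn measured (or synthetic) engineering
stress-strain curves into constitutive parameters:

* :class:`LinearElasticCurveModel` — ordinary least squares through the
  origin over a small-strain window; the slope is the Young's modulus.
* :class:`OgdenCurveModel` — multi-start nonlinear least squares of the
  incompressible uniaxial nominal Ogden response.

Each ``.fit()`` returns a Results object carrying the point estimates,
fit diagnostics (residual norms, convergence history) and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constitutive import (
    LinearElasticParameters,
    OgdenConvention,
    OgdenParameters,
    StressStrainCurve,
    ogden_uniaxial_nominal,
)

__all__ = [
    "LinearElasticCurveModel",
    "LinearElasticCurveResults",
    "OgdenCurveModel",
    "OgdenCurveResults",
    "FitConvergenceError",
]


class FitConvergenceError(RuntimeError):
    """Raised when a curve fit fails; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


class LinearElasticCurveModel:
    """OLS slope through the origin on a strain window.

    Parameters
    ----------
    curve : StressStrainCurve
    strain_window : (lo, hi)
        Inclusive strain interval used for the regression; defaults to
        the initial-slope window [0, 0.02].
    """

    def __init__(self, curve: StressStrainCurve, strain_window=(0.0, 0.02)):
        lo, hi = strain_window
        if not hi > lo:
            raise ValueError("strain_window must satisfy hi > lo")
        mask = (curve.strain >= lo) & (curve.strain <= hi)
        if mask.sum() < 2:
            raise ValueError(
                f"strain window [{lo}, {hi}] contains {int(mask.sum())} points; need >= 2"
            )
        self.curve = curve
        self.strain_window = (float(lo), float(hi))
        self._x = curve.strain[mask]
        self._y = curve.stress[mask]
        if np.allclose(self._x, self._x[0]):
            raise ValueError("zero-variance strain inside window")

    def fit(self) -> "LinearElasticCurveResults":
        x, y = self._x, self._y
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        sigma2 = float(resid @ resid) / dof
        bse = float(np.sqrt(sigma2 / sxx))
        return LinearElasticCurveResults(
            model=self, youngs_modulus=slope, bse=bse, resid=resid, nobs=x.size
        )


@dataclass
class LinearElasticCurveResults:
    model: LinearElasticCurveModel
    youngs_modulus: float
    bse: float
    resid: np.ndarray
    nobs: int

    @property
    def params(self) -> LinearElasticParameters:
        return LinearElasticParameters(youngs_modulus=self.youngs_modulus)

    def summary(self) -> str:
        lo, hi = self.model.strain_window
        lines = [
            "Linear-elastic curve fit (OLS through origin)",
            "=" * 46,
            f"strain window        : [{lo:g}, {hi:g}]",
            f"n observations       : {self.nobs}",
            f"Young's modulus (MPa): {self.youngs_modulus:.6g}",
            f"std. error (MPa)     : {self.bse:.3g}",
            f"residual RMS (MPa)   : {np.sqrt(np.mean(self.resid**2)):.3g}",
        ]
        return "\n".join(lines)


class OgdenCurveModel:
    """Nonlinear least-squares Ogden fit of a nominal stress-strain curve.

    The decision variables are the ``n_terms`` pairs (mu_n, alpha_n);
    the objective is the pointwise mismatch of the incompressible
    uniaxial nominal stress against the curve.  Because the objective is
    non-convex, ``fit`` runs a deterministic multi-start (seeded) and
    keeps the best admissible solution (positive initial shear modulus).
    """

    def __init__(
        self,
        curve: StressStrainCurve,
        n_terms: int = 3,
        convention: OgdenConvention | str = OgdenConvention.SOLVER,
    ):
        if n_terms not in (1, 2, 3):
            raise ValueError("n_terms must be 1, 2 or 3")
        if curve.strain.size < 4 * n_terms:
            raise ValueError(
                f"curve has {curve.strain.size} points; need >= {4 * n_terms} for {n_terms} terms"
            )
        if np.allclose(curve.stress, 0.0):
            raise ValueError("degenerate input: stress is identically zero")
        self.curve = curve
        self.n_terms = n_terms
        self.convention = OgdenConvention(convention)
        self._lam = 1.0 + curve.strain
        self._y = curve.stress
        self._ynorm = float(np.linalg.norm(curve.stress))

    def _params_from_vector(self, x: np.ndarray) -> OgdenParameters | None:
        terms = tuple((x[2 * i], x[2 * i + 1]) for i in range(self.n_terms))
        try:
            return OgdenParameters(terms=terms, convention=self.convention)
        except ValueError:
            return None

    def _residual(self, x: np.ndarray) -> np.ndarray:
        mu = x[0::2]
        al = x[1::2]
        al = np.where(np.abs(al) < 1e-6, 1e-6, al)
        if self.convention is OgdenConvention.CLASSICAL:
            k = mu
        else:
            k = 2.0 * mu / al
        lam = self._lam[:, None]
        with np.errstate(over="ignore", invalid="ignore"):
            model = np.sum(k * (lam**al - lam ** (-al / 2.0)), axis=1) / self._lam
        model = np.nan_to_num(model, nan=1e30, posinf=1e30, neginf=-1e30)
        return model - self._y

    def _starting_points(self, seed: int, n_starts: int) -> list[np.ndarray]:
        # neutral scale: a 1-term neo-Hookean-ish guess from the end slope
        slope = max(self._y[-1] / max(self._lam[-1] - 1.0, 1e-9), 1e-6)
        mu_scale = slope / 3.0
        base_alphas = [2.0, 4.0, -2.0, 8.0, -6.0, 1.0]
        starts: list[np.ndarray] = []
        x0 = np.empty(2 * self.n_terms)
        for i in range(self.n_terms):
            x0[2 * i] = mu_scale / self.n_terms
            x0[2 * i + 1] = base_alphas[i]
        starts.append(x0)
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            x = np.empty(2 * self.n_terms)
            for i in range(self.n_terms):
                x[2 * i] = mu_scale * rng.uniform(0.05, 2.0) * rng.choice([-1, 1])
                x[2 * i + 1] = rng.uniform(-8.0, 8.0)
            starts.append(x)
        return starts

    def fit(self, seed: int = 0, n_starts: int = 12, max_nfev: int = 2000) -> "OgdenCurveResults":
        best = None
        history: list[float] = []
        for x0 in self._starting_points(seed, n_starts):
            try:
                sol = optimize.least_squares(
                    self._residual, x0, method="lm", max_nfev=max_nfev
                )
            except Exception:
                continue
            rn = float(np.linalg.norm(sol.fun))
            history.append(rn)
            params = self._params_from_vector(sol.x)
            if params is None:
                continue
            if best is None or rn < best[0]:
                best = (rn, params, sol)
            if rn < 1e-9 * max(self._ynorm, 1.0):
                break
        if best is None:
            raise FitConvergenceError(
                "Ogden fit failed: no admissible (mu0 > 0) solution found",
                residual_history=history,
            )
        rn, params, sol = best
        return OgdenCurveResults(
            model=self,
            params=params,
            residual_norm=rn,
            relative_residual=rn / max(self._ynorm, 1e-300),
            resid=sol.fun.copy(),
            residual_history=history,
            success=True,
        )


@dataclass
class OgdenCurveResults:
    model: OgdenCurveModel
    params: OgdenParameters
    residual_norm: float
    relative_residual: float
    resid: np.ndarray
    residual_history: list[float]
    success: bool

    def predict(self, stretch=None) -> np.ndarray:
        lam = self.model._lam if stretch is None else np.asarray(stretch)
        return np.asarray(ogden_uniaxial_nominal(self.params, lam))

    def summary(self) -> str:
        lines = [
            f"Ogden curve fit ({self.model.n_terms} terms, {self.params.convention.value} convention)",
            "=" * 54,
            f"residual 2-norm (MPa): {self.residual_norm:.3e}",
            f"relative residual    : {self.relative_residual:.3e}",
            f"multi-starts run     : {len(self.residual_history)}",
            "",
            f"{'term':>4} {'mu (MPa)':>14} {'alpha':>10}",
        ]
        for i, (mu, al) in enumerate(self.params.terms, 1):
            lines.append(f"{i:>4} {mu:>14.6g} {al:>10.5g}")
        from .constitutive import initial_shear_modulus

        lines.append("")
        lines.append(f"initial shear modulus: {initial_shear_modulus(self.params):.6g} MPa")
        return "\n".join(lines)
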