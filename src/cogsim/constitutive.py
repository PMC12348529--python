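"""Material laws for cog-thread and vaginal-wall tissue simulation.

Two constitutive families are supported, in a consistent mm-N-MPa unit
system:

* linear elasticity for the PCL threads (Young's modulus ``E``,
  Poisson's ratio ``nu``), valid because thread simulations stay in the
  elastic range, and
* the incompressible Ogden hyperelastic model for vaginal/uterine
  tissue, written in principal stretches.

Two Ogden parameterizations circulate in the literature and in solver
manuals.  The *classical* form is

    W = sum_n (mu_n / alpha_n) (l1^a_n + l2^a_n + l3^a_n - 3)

while the *solver* (Abaqus-style) form is

    W = sum_n (2 mu_n / alpha_n^2) (l1^a_n + l2^a_n + l3^a_n - 3)

with initial shear modulus ``mu0 = 0.5*sum(mu_n*alpha_n)`` and
``mu0 = sum(mu_n)`` respectively.  The published vagina/uterus parameter
set used throughout this package (three terms, mixed-sign mu_n, negative
alpha_n) is only physically admissible (mu0 > 0) under the solver form,
which is therefore the default; the constructor rejects parameter sets
whose initial shear modulus is not positive.

Tissue damage is modelled as a pure multiplicative stiffness reduction:
every mu_n is scaled by (1 - damage), leaving the exponents untouched,
so the uniaxial stress at any stretch scales by exactly (1 - damage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "OgdenConvention",
    "LinearElasticParameters",
    "OgdenParameters",
    "StressStrainCurve",
    "TABLE_TISSUE_OGDEN",
    "THREAD_LINEAR_ELASTIC",
    "linear_uniaxial_stress",
    "ogden_energy",
    "ogden_uniaxial_cauchy",
    "ogden_uniaxial_nominal",
    "initial_shear_modulus",
    "apply_damage",
    "fit_young_modulus",
    "fit_ogden",
]


class OgdenConvention(str, Enum):
    """Parameterization of the Ogden strain-energy density."""

    CLASSICAL = "classical"
    SOLVER = "solver"


@dataclass(frozen=True)
class LinearElasticParameters:
    """Isotropic linear elasticity (``sigma = E * eps`` uniaxially).

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus ``E`` in MPa.  Must be positive.
    poissons_ratio : float
        Poisson's ratio ``nu``; must lie in (-1, 0.5).
    """

    youngs_modulus: float
    poissons_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError(f"youngs_modulus must be > 0, got {self.youngs_modulus}")
        if not -1.0 < self.poissons_ratio < 0.5:
            raise ValueError(
                f"poissons_ratio must lie in (-1, 0.5), got {self.poissons_ratio}"
            )

    @property
    def lame_lambda(self) -> float:
        E, nu = self.youngs_modulus, self.poissons_ratio
        return E * nu / ((1 + nu) * (1 - 2 * nu))

    @property
    def lame_mu(self) -> float:
        return self.youngs_modulus / (2 * (1 + self.poissons_ratio))


@dataclass(frozen=True)
class OgdenParameters:
    """Ogden hyperelastic parameters (mu_n in MPa, alpha_n dimensionless).

    ``damage_factor`` in [0, 1) scales every mu_n by (1 - damage_factor)
    at evaluation time, implementing the proportional stiffness-loss
    damage model for the impaired anterior vaginal wall.
    """

    terms: tuple[tuple[float, float], ...]
    convention: OgdenConvention = OgdenConvention.SOLVER
    damage_factor: float = 0.0

    def __post_init__(self) -> None:
        terms = tuple((float(m), float(a)) for m, a in self.terms)
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "convention", OgdenConvention(self.convention))
        if len(terms) == 0:
            raise ValueError("OgdenParameters needs at least one (mu, alpha) term")
        if any(a == 0 for _, a in terms):
            raise ValueError("all alpha_n must be nonzero")
        if not 0.0 <= self.damage_factor < 1.0:
            raise ValueError(f"damage_factor must lie in [0, 1), got {self.damage_factor}")
        mu0 = initial_shear_modulus(self, _skip_validation=True)
        if not mu0 > 0:
            raise ValueError(
                f"initial shear modulus must be positive, got {mu0:.4g} MPa "
                f"under the {self.convention.value!r} convention; "
                "this parameter set is not stable in this form"
            )

    @property
    def mus(self) -> np.ndarray:
        """Effective mu_n (MPa), damage applied."""
        return (1.0 - self.damage_factor) * np.array([m for m, _ in self.terms])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for _, a in self.terms])


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering (nominal) stress-strain curve.

    ``strain`` is dimensionless and strictly increasing from 0;
    ``stress`` is in MPa.
    """

    strain: np.ndarray
    stress: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)
        if strain.ndim != 1 or stress.ndim != 1 or strain.shape != stress.shape:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if strain.size < 2:
            raise ValueError("curve needs at least 2 points")
        if strain[0] != 0.0:
            raise ValueError("strain must start at 0")
        if not np.all(np.diff(strain) > 0):
            raise ValueError("strain must be strictly increasing")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"strain": self.strain, "stress_MPa": self.stress}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, label: str = "") -> "StressStrainCurve":
        import pandas as pd

        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["strain", "stress_MPa"]:
            raise ValueError(
                f"expected columns 'strain,stress_MPa', got {list(df.columns)}"
            )
        return cls(df["strain"].to_numpy(), df["stress_MPa"].to_numpy(), label=label)


# ---------------------------------------------------------------------------
# closed-form responses


def linear_uniaxial_stress(params: LinearElasticParameters, strain) -> np.ndarray | float:
    """Uniaxial Hooke's law ``sigma = E * eps`` (MPa)."""
    strain = np.asarray(strain, dtype=float)
    if np.any(strain < 0):
        raise ValueError("strain must be >= 0")
    out = params.youngs_modulus * strain
    return float(out) if out.ndim == 0 else out


def _term_coeffs(params: OgdenParameters) -> tuple[np.ndarray, np.ndarray]:
    """Energy coefficients c_n such that W = sum c_n (l1^a+l2^a+l3^a-3)."""
    mu, al = params.mus, params.alphas
    if params.convention is OgdenConvention.CLASSICAL:
        return mu / al, al
    return 2.0 * mu / al**2, al


def ogden_energy(params: OgdenParameters, stretches: Sequence[float]) -> float:
    """Strain-energy density W (MPa) at principal stretches (l1, l2, l3)."""
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,):
        raise ValueError("stretches must be a triple (l1, l2, l3)")
    if np.any(lam <= 0):
        raise ValueError("principal stretches must be positive")
    c, a = _term_coeffs(params)
    return float(np.sum(c * (np.sum(lam[:, None] ** a[None, :], axis=0) - 3.0)))


def ogden_uniaxial_cauchy(params: OgdenParameters, stretch) -> np.ndarray | float:
    """Incompressible uniaxial Cauchy stress at stretch lambda (MPa).

    Specializes the energy to (l, 1/sqrt(l), 1/sqrt(l)) and eliminates
    the hydrostatic pressure with the traction-free lateral condition,
    giving ``sigma = sum_n k_n (l^a_n - l^(-a_n/2))`` with
    ``k_n = mu_n`` (classical) or ``2 mu_n / alpha_n`` (solver).
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    mu, al = params.mus, params.alphas
    if params.convention is OgdenConvention.CLASSICAL:
        k = mu
    else:
        k = 2.0 * mu / al
    out = np.sum(
        k * (lam[..., None] ** al - lam[..., None] ** (-al / 2.0)), axis=-1
    )
    return float(out) if out.ndim == 0 else out


def ogden_uniaxial_nominal(params: OgdenParameters, stretch) -> np.ndarray | float:
    """Nominal (engineering, first Piola) uniaxial stress: Cauchy / lambda."""
    lam = np.asarray(stretch, dtype=float)
    out = np.asarray(ogden_uniaxial_cauchy(params, lam)) / lam
    return float(out) if out.ndim == 0 else out


def initial_shear_modulus(params: OgdenParameters, *, _skip_validation: bool = False) -> float:
    """Ground-state shear modulus mu0 (MPa).

    classical: mu0 = 0.5 * sum(mu_n * alpha_n);  solver: mu0 = sum(mu_n).
    """
    if _skip_validation:
        mu = (1.0 - params.damage_factor) * np.array([m for m, _ in params.terms])
        al = np.array([a for _, a in params.terms])
        conv = OgdenConvention(params.convention)
    else:
        mu, al, conv = params.mus, params.alphas, params.convention
    if conv is OgdenConvention.CLASSICAL:
        return float(0.5 * np.sum(mu * al))
    return float(np.sum(mu))


def apply_damage(params: OgdenParameters, reduction: float) -> OgdenParameters:
    """Return parameters with stiffness reduced by ``reduction`` in [0, 1).

    Composes multiplicatively with any damage already stored, so the
    uniaxial stress of the result is exactly ``(1 - reduction)`` times
    that of ``params`` at every stretch.
    """
    if not 0.0 <= reduction < 1.0:
        raise ValueError(f"reduction must lie in [0, 1), got {reduction}")
    new_damage = 1.0 - (1.0 - params.damage_factor) * (1.0 - reduction)
    return replace(params, damage_factor=new_damage)


#: Three-term Ogden parameter set for vagina/uterus tissue (MPa), solver
#: convention; initial shear modulus 1.73 MPa.
TABLE_TISSUE_OGDEN = OgdenParameters(
    terms=((-92.24, -3.41), (39.29, -0.66), (54.68, -6.48)),
    convention=OgdenConvention.SOLVER,
)

#: Linear-elastic PCL thread material: E from the initial slope of the
#: uncut-filament tensile curve, nu = 0.3.
THREAD_LINEAR_ELASTIC = LinearElasticParameters(youngs_modulus=367.69, poissons_ratio=0.3)


# ---------------------------------------------------------------------------
# curve fitting (delegates to the model objects in cogsim.fitting)


def fit_young_modulus(
    curve: StressStrainCurve, strain_window: tuple[float, float] = (0.0, 0.02)
) -> LinearElasticParameters:
    """Least-squares initial slope of a stress-strain curve.

    Fits ``sigma = E * eps`` through the origin using the points whose
    strain lies inside ``strain_window`` (inclusive) and returns the
    slope as a Young's modulus with the default Poisson's ratio.
    """
    from .fitting import LinearElasticCurveModel

    res = LinearElasticCurveModel(curve, strain_window=strain_window).fit()
    return LinearElasticParameters(youngs_modulus=res.youngs_modulus)


def fit_ogden(
    curve: StressStrainCurve,
    n_terms: int = 3,
    convention: OgdenConvention | str = OgdenConvention.SOLVER,
    seed: int = 0,
):
    """Nonlinear least-squares Ogden fit of a nominal stress-strain curve.

    Returns an :class:`~cogsim.fitting.OgdenCurveResults`; its ``params``
    attribute holds the fitted :class:`OgdenParameters`.  Raises
    :class:`~cogsim.fitting.FitConvergenceError` (which carries the
    residual history) if no admissible fit is found.
    """
    from .fitting import OgdenCurveModel

    return OgdenCurveModel(curve, n_terms=n_terms, convention=convention).fit(seed=seed)
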