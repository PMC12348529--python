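"""Closed-form constitutive laws: values, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogsim.constitutive import (
    LinearElasticParameters,
    OgdenConvention,
    OgdenParameters,
    StressStrainCurve,
    TABLE_TISSUE_OGDEN,
    apply_damage,
    initial_shear_modulus,
    linear_uniaxial_stress,
    ogden_energy,
    ogden_uniaxial_cauchy,
    ogden_uniaxial_nominal,
)

TISSUE_TERMS = ((-92.24, -3.41), (39.29, -0.66), (54.68, -6.48))


class TestLinearElastic:
    @pytest.mark.parametrize(
        "E, eps, expected",
        [(367.69, 0.0, 0.0), (367.69, 0.01, 3.6769), (2.0, 0.5, 1.0)],
    )
    def test_hookes_law(self, E, eps, expected):
        p = LinearElasticParameters(youngs_modulus=E)
        assert linear_uniaxial_stress(p, eps) == pytest.approx(expected, rel=1e-12)

    def test_negative_strain_rejected(self):
        with pytest.raises(ValueError):
            linear_uniaxial_stress(LinearElasticParameters(1.0), -0.1)

    @pytest.mark.parametrize("E, nu", [(-1.0, 0.3), (1.0, 0.5), (1.0, -1.0)])
    def test_invalid_parameters_rejected(self, E, nu):
        with pytest.raises(ValueError):
            LinearElasticParameters(youngs_modulus=E, poissons_ratio=nu)


class TestOgdenEnergy:
    def test_undeformed_state_is_stress_free(self, tissue):
        assert ogden_energy(tissue, (1.0, 1.0, 1.0)) == pytest.approx(0.0, abs=1e-14)
        assert ogden_uniaxial_cauchy(tissue, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert ogden_uniaxial_nominal(tissue, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_term_closed_form(self):
        # solver convention, mu=1, alpha=2: W = 1/2 (sum lam^2 - 3)
        p = OgdenParameters(terms=((1.0, 2.0),), convention="solver")
        lam = (2.0, 2**-0.5, 2**-0.5)
        assert ogden_energy(p, lam) == pytest.approx(1.0, rel=1e-12)

    def test_tissue_energy_against_term_by_term_oracle(self, tissue):
        # high-precision term-by-term evaluation with sympy
        import sympy as sp

        lam = (1.1, 1.1**-0.5, 1.1**-0.5)
        total = sp.Integer(0)
        for mu, al in TISSUE_TERMS:
            mu_, al_ = sp.Rational(str(mu)), sp.Rational(str(al))
            s = sum(sp.Float(l, 50) ** al_ for l in lam)
            total += 2 * mu_ / al_**2 * (s - 3)
        expected = float(total.evalf(50))
        assert ogden_energy(tissue, lam) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_stretch_rejected(self, tissue):
        with pytest.raises(ValueError):
            ogden_energy(tissue, (1.0, -0.5, 1.0))
        with pytest.raises(ValueError):
            ogden_uniaxial_cauchy(tissue, 0.0)


class TestUniaxialStress:
    @pytest.mark.parametrize("lam", [0.7, 0.9, 1.1, 1.5])
    @pytest.mark.parametrize("convention", ["solver", "classical"])
    def test_cauchy_matches_energy_derivative(self, lam, convention):
        # sigma = lam dW/dlam along the incompressible uniaxial path
        if convention == "classical":
            params = OgdenParameters(terms=((0.3, 2.0), (0.05, -2.0)), convention=convention)
        else:
            params = TABLE_TISSUE_OGDEN

        def W(l):
            return ogden_energy(params, (l, l**-0.5, l**-0.5))

        h = 1e-6
        oracle = lam * (W(lam + h) - W(lam - h)) / (2 * h)
        assert ogden_uniaxial_cauchy(params, lam) == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("lam", [0.8, 1.2])
    def test_nominal_matches_energy_derivative(self, tissue, lam):
        # nominal (first Piola) stress P = dW/dlam
        def W(l):
            return ogden_energy(tissue, (l, l**-0.5, l**-0.5))

        h = 1e-6
        oracle = (W(lam + h) - W(lam - h)) / (2 * h)
        assert ogden_uniaxial_nominal(tissue, lam) == pytest.approx(oracle, rel=1e-6)

    def test_neo_hookean_limit(self):
        # single term mu=G, alpha=2, solver convention: sigma = G(lam^2 - 1/lam)
        G = 0.7
        p = OgdenParameters(terms=((G, 2.0),), convention="solver")
        for lam in (0.8, 1.0, 1.3):
            assert ogden_uniaxial_cauchy(p, lam) == pytest.approx(
                G * (lam**2 - 1 / lam), rel=1e-12
            )

    @given(lam=st.floats(0.5, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_nominal_times_stretch_equals_cauchy(self, lam):
        p = TABLE_TISSUE_OGDEN
        assert ogden_uniaxial_nominal(p, lam) * lam == pytest.approx(
            ogden_uniaxial_cauchy(p, lam), rel=1e-12, abs=1e-12
        )

    def test_tissue_nominal_stress_monotone_in_working_range(self, tissue):
        lam = np.linspace(1.0, 1.6, 400)
        nominal = ogden_uniaxial_nominal(tissue, lam)
        assert np.all(np.diff(nominal) > 0)

    def test_small_strain_slope_is_three_mu0(self, tissue):
        # incompressible uniaxial Young's modulus = 3 x shear modulus
        h = 1e-4
        slope = (
            ogden_uniaxial_cauchy(tissue, 1 + h) - ogden_uniaxial_cauchy(tissue, 1 - h)
        ) / (2 * h)
        assert slope == pytest.approx(3.0 * initial_shear_modulus(tissue), rel=0.01)


class TestInitialShearModulus:
    def test_single_term_classical(self):
        p = OgdenParameters(terms=((3.0, 2.0),), convention="classical")
        assert initial_shear_modulus(p) == pytest.approx(3.0)

    def test_tissue_solver_convention(self, tissue):
        assert initial_shear_modulus(tissue) == pytest.approx(1.73, abs=1e-10)

    def test_tissue_classical_convention_rejected(self):
        # 0.5 sum(mu_n alpha_n) = -32.86 MPa < 0: unstable, must be refused
        direct = 0.5 * sum(m * a for m, a in TISSUE_TERMS)
        assert direct == pytest.approx(-32.8597, abs=1e-4)
        with pytest.raises(ValueError, match="shear modulus"):
            OgdenParameters(terms=TISSUE_TERMS, convention="classical")

    def test_constructor_rejects_degenerate_terms(self):
        with pytest.raises(ValueError):
            OgdenParameters(terms=())
        with pytest.raises(ValueError):
            OgdenParameters(terms=((1.0, 0.0),))


class TestDamage:
    def test_zero_reduction_is_identity(self, tissue):
        out = apply_damage(tissue, 0.0)
        lam = np.linspace(0.7, 1.5, 9)
        assert np.allclose(
            ogden_uniaxial_cauchy(out, lam), ogden_uniaxial_cauchy(tissue, lam)
        )

    @given(
        reduction=st.floats(0.0, 0.95),
        lam=st.floats(0.6, 1.8),
    )
    @settings(max_examples=50, deadline=None)
    def test_stress_scales_by_one_minus_reduction(self, reduction, lam):
        healthy = TABLE_TISSUE_OGDEN
        damaged = apply_damage(healthy, reduction)
        s_h = ogden_uniaxial_cauchy(healthy, lam)
        s_d = ogden_uniaxial_cauchy(damaged, lam)
        assert s_d == pytest.approx((1 - reduction) * s_h, rel=1e-12, abs=1e-14)

    def test_half_damage_halves_tissue_stress(self, tissue):
        damaged = apply_damage(tissue, 0.5)
        for lam in (1.05, 1.2, 1.45):
            assert ogden_uniaxial_cauchy(damaged, lam) == pytest.approx(
                0.5 * ogden_uniaxial_cauchy(tissue, lam), rel=1e-12
            )

    def test_mu_scaling_equivalence(self):
        a = OgdenParameters(terms=((2.0, 2.0),))
        b = OgdenParameters(terms=((1.5, 2.0),))
        damaged = apply_damage(a, 0.25)
        lam = np.linspace(0.8, 1.4, 7)
        assert np.allclose(
            ogden_uniaxial_cauchy(damaged, lam), ogden_uniaxial_cauchy(b, lam)
        )

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_reduction_rejected(self, tissue, bad):
        with pytest.raises(ValueError):
            apply_damage(tissue, bad)


class TestStressStrainCurve:
    def test_validation(self):
        with pytest.raises(ValueError):
            StressStrainCurve(strain=np.array([0.1, 0.2]), stress=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            StressStrainCurve(strain=np.array([0.0, 0.0]), stress=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            StressStrainCurve(strain=np.array([0.0]), stress=np.array([0.0]))

    def test_csv_round_trip(self, tmp_path, tissue):
        from cogsim.synthetic import generate_stress_strain_curve

        curve = generate_stress_strain_curve(tissue, 0.2, 20, noise_sd=0.01, seed=3)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = StressStrainCurve.from_csv(path)
        assert np.allclose(back.strain, curve.strain)
        assert np.allclose(back.stress, curve.stress)
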