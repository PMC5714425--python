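"""TG-43U1 engine: geometry function, interpolators, dose rate, superposition."""

import numpy as np
import pytest
from scipy import integrate

import isakernel as ik
from isakernel.tg43 import DegenerateGeometryError


def line_integral_oracle(r, theta_deg, L):
    """Independent geometry-function oracle: numerically integrate
    1/|x - l|^2 along the active line, divide by L."""
    th = np.radians(theta_deg)
    rho, z = r * np.sin(th), r * np.cos(th)
    val, _ = integrate.quad(lambda l: 1.0 / (rho**2 + (z - l) ** 2),
                            -L / 2, L / 2, epsabs=1e-14, epsrel=1e-13)
    return val / L


class TestEffectiveLength:
    @pytest.mark.parametrize("n, spacing, expected", [
        (3, 0.110, 0.330),   # three pellets at 1.10 mm pitch
        (1, 0.35, 0.35),
        (5, 0.1, 0.5),
    ])
    def test_values(self, n, spacing, expected):
        assert ik.effective_length(n, spacing) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n, spacing", [(0, 0.1), (-1, 0.1), (3, 0.0), (2, -1.0)])
    def test_invalid(self, n, spacing):
        with pytest.raises(ValueError):
            ik.effective_length(n, spacing)


class TestGeometryFunction:
    def test_matches_line_integral_oracle(self, rng):
        for _ in range(100):
            r = rng.uniform(0.3, 10.0)
            th = rng.uniform(2.0, 178.0)
            L = rng.choice([0.33, 0.35])
            got = ik.geometry_function_line(r, th, L)
            want = line_integral_oracle(r, th, L)
            assert got == pytest.approx(want, abs=1e-9)

    def test_point_source_limit(self):
        # L -> 0 recovers inverse square
        for r, th in [(1.0, 90.0), (2.5, 40.0), (0.7, 135.0)]:
            g = ik.geometry_function_line(r, th, 1e-5)
            assert abs(g - 1.0 / r**2) / (1.0 / r**2) < 1e-6

    def test_axial_limiting_form(self):
        L = 0.35
        g = ik.geometry_function_line(1.0, 0.0, L)
        assert g == pytest.approx(1.0 / (1.0 - L**2 / 4), rel=1e-12)

    def test_point_on_segment_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            ik.geometry_function_line(0.1, 0.0, 0.35)

    def test_transverse_values_frozen(self):
        # frozen from the quadrature oracle above
        assert ik.geometry_function_line(1, 90, 0.35) == pytest.approx(
            0.9899752368706569, abs=1e-12)
        assert ik.geometry_function_line(2, 90, 0.35) == pytest.approx(
            0.2493648941413184, abs=1e-12)


class TestInterpolators:
    def test_radial_exact_at_knots(self, params_i125, params_ir192):
        for params in (params_i125, params_ir192):
            tab = params.radial_table
            got = ik.interp_radial(params, tab["r_cm"].to_numpy())
            np.testing.assert_allclose(got, tab["gL"].to_numpy(), rtol=1e-12)

    def test_radial_normalization_at_r0(self, params_i125, params_ir192):
        for params in (params_i125, params_ir192):
            assert ik.interp_radial(params, 1.0) == pytest.approx(1.0, abs=5e-3)

    def test_radial_log_linear_midpoint(self, params_i125):
        # log-linear rule: midpoint in r gives the geometric mean of knots
        tab = params_i125.radial_table
        r0, r1 = tab["r_cm"].iloc[2], tab["r_cm"].iloc[3]
        g0, g1 = tab["gL"].iloc[2], tab["gL"].iloc[3]
        mid = ik.interp_radial(params_i125, (r0 + r1) / 2)
        assert mid == pytest.approx(np.sqrt(g0 * g1), rel=1e-12)

    def test_radial_invalid_and_clamped(self, params_i125):
        with pytest.raises(ValueError):
            ik.interp_radial(params_i125, -1.0)
        with pytest.warns(UserWarning):
            far = ik.interp_radial(params_i125, 50.0)
        assert far == pytest.approx(params_i125.radial_table["gL"].iloc[-1])

    def test_anisotropy_exact_at_knots(self, params_ir192):
        tab = params_ir192.anisotropy_table
        got = ik.interp_anisotropy(params_ir192, tab["r_cm"].to_numpy(),
                                   tab["theta_deg"].to_numpy())
        np.testing.assert_allclose(got, tab["F"].to_numpy(), rtol=1e-12)

    def test_anisotropy_unity_on_transverse_axis(self, params_i125, params_ir192):
        for params in (params_i125, params_ir192):
            for r in (0.6, 1.0, 2.7, 4.9):
                assert ik.interp_anisotropy(params, r, 90.0) == pytest.approx(
                    1.0, abs=5e-3)

    def test_anisotropy_pole_symmetry(self, params_i125, rng):
        for _ in range(20):
            r = rng.uniform(0.5, 5.0)
            th = rng.uniform(0.0, 90.0)
            a = ik.interp_anisotropy(params_i125, r, th)
            b = ik.interp_anisotropy(params_i125, r, 180.0 - th)
            assert a == pytest.approx(b, rel=1e-10)


class TestDoseRate:
    def test_reference_point_identity(self, params_i125, params_ir192):
        # at (1 cm, 90 deg), G ratio = g = F = 1, so dose = Lambda * Sk
        for params in (params_i125, params_ir192):
            d = ik.dose_rate_single(params, 2.5, ik.DosePoint(1.0, 90.0))
            assert d / (params.dose_rate_constant * 2.5) == pytest.approx(
                1.0, abs=1e-12)

    def test_linearity_in_strength(self, params_i125):
        pt = ik.DosePoint(2.0, 50.0)
        d1 = ik.dose_rate_single(params_i125, 1.0, pt)
        d2 = ik.dose_rate_single(params_i125, 2.0, pt)
        assert d2 == pytest.approx(2 * d1, rel=1e-14)
        assert ik.dose_rate_single(params_i125, 0.0, pt) == 0.0

    def test_dose_point_from_away_along(self):
        p = ik.DosePoint.from_away_along(1.0, 1.0)
        assert p.r == pytest.approx(np.sqrt(2))
        assert p.theta == pytest.approx(45.0)
        assert ik.DosePoint.from_away_along(1.0, 0.0).theta == pytest.approx(90.0)


class TestSuperpose:
    def grid(self):
        return ik.standard_grid(extent_cm=3.0)

    def test_single_seed_matches_dose_rate_single(self, params_i125):
        plan = ik.ImplantPlan([ik.PlanSeed("a", [0, 0, 0], 1.0)], "I125_6702")
        g = ik.superpose(params_i125, plan, self.grid())
        got = g.value_at((0, 2.0, 1.0))
        want = ik.dose_rate_single(params_i125, 1.0,
                                   ik.DosePoint.from_away_along(2.0, 1.0))
        assert got == pytest.approx(want, rel=1e-12)

    def test_linearity_split_strength(self, params_i125):
        plan1 = ik.ImplantPlan([ik.PlanSeed("a", [0, 0.5, 0], 2.0)], "I125_6702")
        # two seeds with Sk/2 at symmetric positions vs sum of singles
        plan2 = ik.ImplantPlan([ik.PlanSeed("a", [0, 0.5, 0], 1.0),
                                ik.PlanSeed("b", [0, 0.5, 0.5], 1.0)],
                               "I125_6702")
        planb = ik.ImplantPlan([ik.PlanSeed("b", [0, 0.5, 0.5], 1.0)],
                               "I125_6702")
        plana = ik.ImplantPlan([ik.PlanSeed("a", [0, 0.5, 0], 1.0)],
                               "I125_6702")
        g = self.grid()
        total = ik.superpose(params_i125, plan2, g).values
        parts = (ik.superpose(params_i125, plana, g).values
                 + ik.superpose(params_i125, planb, g).values)
        np.testing.assert_allclose(total, parts, rtol=1e-12)
        half = ik.superpose(params_i125, plan1, g).values
        np.testing.assert_allclose(half, 2 * ik.superpose(
            params_i125, plana, g).values, rtol=1e-12)

    def test_permutation_invariance(self, params_ir192):
        seeds = [ik.PlanSeed("a", [0, -1, 0], 1.0),
                 ik.PlanSeed("b", [0, 1, 0], 2.0),
                 ik.PlanSeed("c", [0, 0, 1], 0.5)]
        g = self.grid()
        v1 = ik.superpose(params_ir192,
                          ik.ImplantPlan(seeds, "Ir192_Flexisource"), g).values
        v2 = ik.superpose(params_ir192,
                          ik.ImplantPlan(seeds[::-1], "Ir192_Flexisource"),
                          g).values
        np.testing.assert_array_equal(v1, v2)

    def test_overlapping_seeds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ik.ImplantPlan([ik.PlanSeed("a", [0, 0, 0], 1.0),
                            ik.PlanSeed("b", [0, 0.001, 0], 1.0)], "I125_6702")

    def test_dose_non_negative(self, params_i125):
        plan = ik.ImplantPlan([ik.PlanSeed("a", [0, 0.5, 0.5], 1.0)],
                              "I125_6702")
        g = ik.superpose(params_i125, plan, self.grid())
        assert np.all(g.values >= 0)
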