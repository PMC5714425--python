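"""Multiplicative P-value model: combination, shadow rule, kernels, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isakernel as ik
from isakernel.isa import MissingKernelError, SCATTER_EPS, shadow_mask


class TestCombine:
    @pytest.mark.parametrize("factors, expected", [
        ([0.866, 0.910, 0.935, 0.946], 0.697),   # printed case-2 product
        ([0.890, 0.898, 0.933, 0.939], 0.700),
        ([0.640, 0.999, 1, 1, 1, 1, 1], 0.639),
        ([], 1.0),
    ])
    def test_products(self, factors, expected):
        assert round(ik.combine_pvalues(factors), 3) == expected

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.03, 2.0])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            ik.combine_pvalues([0.9, bad])

    def test_accepts_scatter_excess(self):
        assert ik.combine_pvalues([1.015]) == pytest.approx(1.015)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), max_size=8))
    def test_commutative_and_bounded(self, ps):
        a = ik.combine_pvalues(ps)
        b = ik.combine_pvalues(list(reversed(ps)))
        assert a == b
        if ps:
            assert a <= min(ps) + 1e-15

    def test_isa_complement(self):
        assert ik.isa_value(1.0) == 0.0
        assert ik.isa_value(0.697) == pytest.approx(0.303)
        assert ik.isa_value(0.95) == pytest.approx(0.05)
        # ISA + P = 1 exactly
        for p in (0.64, 0.803, 0.999):
            assert ik.isa_value(p) + p == 1.0


class TestShadowRule:
    def test_dummy_off_the_ray(self, seed_6702):
        # dummy in another quadrant: line of sight to a point on Z = 2 is clear
        assert not ik.shadow_test([0, 0, 0], seed_6702, [0, 0.5, -0.5],
                                  [0, 1.0, 2.0])

    def test_dummy_on_segment_midpoint(self, seed_6702):
        assert ik.shadow_test([0, 0, 0], seed_6702, [0, 0.5, 0.5],
                              [0, 1.0, 1.0])

    def test_dummy_behind_active(self, seed_6702):
        assert not ik.shadow_test([0, 0, 0], seed_6702, [0, -1.0, -1.0],
                                  [0, 1.0, 1.0])

    def test_finite_source_widening(self, seed_6702):
        # a dummy sitting just above the center line of sight is picked up
        # only when emission points sampled off the seed center are used
        active_pos = np.zeros(3)
        dummy_pos = np.array([0.0, 0.5, 0.3])
        point = np.array([0.0, 1.0, 0.0])
        narrow = ik.shadow_test(active_pos, seed_6702, dummy_pos, point)
        sources = active_pos + np.array([[0, 0, 0.14], [0, 0, -0.14]])
        wide = ik.shadow_test(active_pos, seed_6702, dummy_pos, point,
                              source_points=sources)
        assert wide and not narrow

    def test_point_at_active_rejected(self, seed_6702):
        with pytest.raises(ValueError):
            ik.shadow_test([0, 0, 0], seed_6702, [0, 1, 0], [0, 0, 0])


@pytest.fixture(scope="module")
def analytic_bank():
    """Small analytic kernel bank for the Flexisource at a few offsets."""
    model = ik.build_flexisource()
    spec = ik.load_spectrum("Ir192_Flexisource")
    grid = ik.standard_grid(extent_cm=4.0)
    bank = ik.KernelBank("Ir192_Flexisource")
    for off in ([0.0, 0.5, 0.5], [0.0, 1.0, 0.0], [0.0, 0.0, 0.5]):
        bank.add(ik.analytic_kernel(model, model, off, spec, grid,
                                    medium=ik.get_material("water")))
    return bank


class TestKernelLookup:
    def test_short_circuit_exact_unity(self, analytic_bank, seed_flexi):
        # wherever shadow_test is false the lookup must be exactly 1.0
        pts = np.array([[0, -1, -1], [0, 2, -2], [0, 0.1, 3.0], [0, 3, 0.2]])
        for off in ([0, 0.5, 0.5], [0, 1.0, 0.0]):
            mask = shadow_mask(np.zeros(3), seed_flexi, np.array(off, float), pts)
            for p, hit in zip(pts, mask):
                val = ik.lookup_p(analytic_bank, off, p)
                if not hit:
                    assert val == 1.0
                else:
                    assert val < 1.0

    def test_nonunity_only_in_shadow_cone(self, analytic_bank, seed_flexi):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-3.5, 3.5, size=(300, 3)) * np.array([0, 1, 1])
        off = np.array([0.0, 1.0, 0.0])
        vals = analytic_bank.p_values(off, pts)
        mask = shadow_mask(np.zeros(3), seed_flexi, off, pts)
        assert np.all(vals[~mask] == 1.0)
        assert np.all(vals <= 1.0 + SCATTER_EPS)

    def test_mirror_and_rotation_symmetry(self, analytic_bank):
        # dummy reflected in Z or rotated about the seed axis reuses the
        # stored quadrant kernel
        p = ik.lookup_p(analytic_bank, [0, 0.5, 0.5], [0, 1.0, 1.0])
        p_mirror = ik.lookup_p(analytic_bank, [0, 0.5, -0.5], [0, 1.0, -1.0])
        p_rot = ik.lookup_p(analytic_bank, [0, -0.5, 0.5], [0, -1.0, 1.0])
        p_out = ik.lookup_p(analytic_bank, [0.5, 0.0, 0.5], [1.0, 0.0, 1.0])
        assert p < 1.0
        assert p_mirror == pytest.approx(p, rel=1e-12)
        assert p_rot == pytest.approx(p, rel=1e-12)
        assert p_out == pytest.approx(p, rel=1e-12)

    def test_off_lattice_and_coverage_errors(self, analytic_bank):
        with pytest.raises(MissingKernelError, match="lattice"):
            ik.lookup_p(analytic_bank, [0, 0.61, 0.5], [0, 2, 2])
        with pytest.raises(MissingKernelError, match="coverage"):
            ik.lookup_p(analytic_bank, [0, 5.0, 4.0], [0, 7.5, 6.0])
        with pytest.raises(MissingKernelError, match="no kernel"):
            ik.lookup_p(analytic_bank, [0, 2.0, 2.0], [0, 4, 4])

    def test_bank_save_load_round_trip(self, analytic_bank, tmp_path):
        analytic_bank.save(tmp_path / "bank")
        back = ik.KernelBank.load(tmp_path / "bank")
        assert len(back) == len(analytic_bank)
        pts = np.array([[0, 1.2, 1.2], [0, 2.0, 0.1], [0, -1, 2]])
        for off in ([0, 0.5, 0.5], [0, 1.0, 0.0], [0, 0.0, 0.5]):
            np.testing.assert_array_equal(back.p_values(off, pts),
                                          analytic_bank.p_values(off, pts))


class TestPModel:
    def plan(self):
        return ik.ImplantPlan(
            [ik.PlanSeed("A", [0, 0, 0], 1.0),
             ik.PlanSeed("B", [0, 0.5, 0.5], 1.0),
             ik.PlanSeed("C", [0, 1.0, 0.0], 1.0)], "Ir192_Flexisource")

    def test_single_seed_plan_is_unity(self, analytic_bank):
        plan = ik.ImplantPlan([ik.PlanSeed("A", [0, 0, 0], 1.0)],
                              "Ir192_Flexisource")
        assert ik.p_model_at(plan, "A", [0, 2, 0], analytic_bank) == 1.0

    def test_product_of_individual_lookups(self, analytic_bank):
        plan = self.plan()
        pt = np.array([0, 2.0, 0.5])
        expected = (ik.lookup_p(analytic_bank, [0, 0.5, 0.5], pt)
                    * ik.lookup_p(analytic_bank, [0, 1.0, 0.0], pt))
        assert ik.p_model_at(plan, "A", pt, analytic_bank) == pytest.approx(
            expected, rel=1e-14)

    def test_neglect_threshold_policy(self, analytic_bank):
        plan = self.plan()
        pt = np.array([0, 3.0, 0.1])
        raw = ik.p_model_at(plan, "A", pt, analytic_bank)
        neglected = ik.p_model_at(plan, "A", pt, analytic_bank,
                                  neglect_threshold=0.96)
        assert neglected >= raw
        # with threshold 0, every factor collapses to 1
        assert ik.p_model_at(plan, "A", pt, analytic_bank,
                             neglect_threshold=0.0) == 1.0

    def test_missing_kernel_propagates(self, analytic_bank):
        plan = ik.ImplantPlan([ik.PlanSeed("A", [0, 0, 0], 1.0),
                               ik.PlanSeed("B", [0, 2.0, 2.0], 1.0)],
                              "Ir192_Flexisource")
        with pytest.raises(MissingKernelError):
            ik.p_model_at(plan, "A", [0, 4, 4], analytic_bank)


class TestCorrectedDose:
    def test_unity_bank_reduces_to_superposition(self, params_ir192):
        grid = ik.standard_grid(extent_cm=3.0)
        plan = ik.ImplantPlan([ik.PlanSeed("A", [0, -0.5, 0], 1.0),
                               ik.PlanSeed("B", [0, 0.5, 0], 1.0)],
                              "Ir192_Flexisource")
        bank = ik.KernelBank.unity("Ir192_Flexisource", grid)
        corr = ik.corrected_dose(plan, grid, params_ir192, bank)
        plain = ik.superpose(params_ir192, plan, grid)
        np.testing.assert_array_equal(corr.values, plain.values)

    def test_correction_never_increases_dose(self, params_ir192, analytic_bank):
        grid = ik.standard_grid(extent_cm=3.0)
        plan = ik.ImplantPlan([ik.PlanSeed("A", [0, -0.25, 0], 1.0),
                               ik.PlanSeed("B", [0, 0.75, 0], 1.0)],
                              "Ir192_Flexisource")
        corr = ik.corrected_dose(plan, grid, params_ir192, analytic_bank)
        plain = ik.superpose(params_ir192, plan, grid)
        ok = np.isfinite(plain.values)
        assert np.all(corr.values[ok] <= plain.values[ok] + 1e-12)
        assert np.any(corr.values[ok] < plain.values[ok])

    def test_single_seed_uncorrected(self, params_ir192, analytic_bank):
        grid = ik.standard_grid(extent_cm=2.0)
        plan = ik.ImplantPlan([ik.PlanSeed("A", [0, 0.5, 0], 1.0)],
                              "Ir192_Flexisource")
        corr = ik.corrected_dose(plan, grid, params_ir192, analytic_bank)
        plain = ik.superpose(params_ir192, plan, grid)
        np.testing.assert_array_equal(corr.values, plain.values)
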