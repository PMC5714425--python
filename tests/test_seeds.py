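"""Seed solid models and ray-path machinery vs a ray-marching oracle."""

import numpy as np
import pytest

import isakernel as ik
from isakernel.materials import get_material
from isakernel.seeds import (Cylinder, ConeFrustum, Hemisphere, Sphere,
                             component_chords, segment_hits)


def _inside(shape, pts):
    """Point-membership oracle, independent of the interval intersection code."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if isinstance(shape, Cylinder):
        return (x**2 + y**2 <= shape.radius**2) & (z >= shape.z0) & (z <= shape.z1)
    if isinstance(shape, Sphere):
        return x**2 + y**2 + (z - shape.cz) ** 2 <= shape.radius**2
    if isinstance(shape, Hemisphere):
        return ((x**2 + y**2 + (z - shape.cz) ** 2 <= shape.radius**2)
                & (shape.sign * (z - shape.cz) >= 0))
    if isinstance(shape, ConeFrustum):
        k = (shape.r1 - shape.r0) / (shape.z1 - shape.z0)
        rad = shape.r0 + k * (z - shape.z0)
        lo, hi = min(shape.z0, shape.z1), max(shape.z0, shape.z1)
        return (x**2 + y**2 <= rad**2) & (z >= lo) & (z <= hi)
    raise TypeError


def marching_path_lengths(seed, ray, length=1.6, step=2e-5):
    """Brute-force oracle: midpoint sampling at ``step`` cm resolution."""
    ts = (np.arange(int(length / step)) + 0.5) * step
    pts = ray.origin[None, :] + ts[:, None] * ray.direction[None, :]
    lengths = {}
    for comp in seed.components:
        n = int(np.count_nonzero(_inside(comp.shape, pts)))
        if n == 0:
            continue
        lengths[comp.material] = lengths.get(comp.material, 0.0) + n * step
        if comp.parent_material is not None:
            lengths[comp.parent_material] = (
                lengths.get(comp.parent_material, 0.0) - n * step)
    return {m: v for m, v in lengths.items() if v > 1e-7 and m != "vacuum"}


class TestBuildModels:
    def test_6702_dimensions(self, seed_6702):
        assert seed_6702.overall_length_cm == pytest.approx(0.460)
        assert seed_6702.outer_diameter_cm == pytest.approx(0.080)
        assert seed_6702.active_length_cm == pytest.approx(0.330)
        # capsule wall: tube outer minus inner radius
        tube = seed_6702.components[0].shape
        inner = seed_6702.components[1].shape
        assert tube.radius - inner.radius == pytest.approx(0.0050)
        # axial extent of the components matches the overall length
        zmax = max(c.shape.cz + c.shape.radius
                   for c in seed_6702.components
                   if isinstance(c.shape, Hemisphere))
        assert 2 * zmax == pytest.approx(0.460)
        # three resin pellets at 1.10 mm pitch, 0.600 mm diameter
        pellets = [c.shape for c in seed_6702.components
                   if c.material == "resin"]
        assert [p.cz for p in pellets] == pytest.approx([-0.110, 0.0, 0.110])
        assert all(p.radius == pytest.approx(0.030) for p in pellets)

    def test_flexisource_dimensions(self, seed_flexi):
        assert seed_flexi.overall_length_cm == pytest.approx(0.460)
        assert seed_flexi.outer_diameter_cm == pytest.approx(0.085)
        assert seed_flexi.active_length_cm == pytest.approx(0.350)
        core = next(c.shape for c in seed_flexi.components
                    if c.material == "iridium")
        assert core.z1 - core.z0 == pytest.approx(0.350)
        assert core.radius == pytest.approx(0.030)
        assert get_material("iridium").density == pytest.approx(22.42)
        cable = seed_flexi.components[-1].shape
        assert cable.z1 - cable.z0 == pytest.approx(0.50)
        assert cable.radius == pytest.approx(0.025)

    def test_steel_composition(self):
        comp = get_material("steel304").composition
        assert comp["Fe"] == pytest.approx(0.6792)
        assert comp["Cr"] == pytest.approx(0.19)
        assert get_material("steel304").density == pytest.approx(8.0)

    def test_json_round_trip(self, seed_flexi, tmp_path):
        seed_flexi.to_json(tmp_path / "flexi.json")
        back = ik.SeedModel.from_json(tmp_path / "flexi.json")
        ray = ik.Ray([-1, 0.02, 0.01], [1, 0.1, 0.05])
        assert ik.ray_path_lengths(back, ray) == ik.ray_path_lengths(seed_flexi, ray)


class TestRayPathLengths:
    def test_miss_returns_empty(self, seed_6702):
        assert ik.ray_path_lengths(seed_6702, ik.Ray([0, 1, 0], [0, 0, 1])) == {}

    def test_perpendicular_diameter_chord(self, seed_6702, seed_flexi):
        # through the tube axis: titanium chord = 2 walls, resin = pellet diameter
        pl = ik.ray_path_lengths(seed_6702, ik.Ray([-1, 0, 0], [1, 0, 0]))
        assert pl["titanium"] == pytest.approx(0.010, abs=1e-12)
        assert pl["resin"] == pytest.approx(0.060, abs=1e-12)
        pl = ik.ray_path_lengths(seed_flexi, ik.Ray([-1, 0, 0], [1, 0, 0]))
        assert pl["steel304"] == pytest.approx(2 * (0.0425 - 0.0335), abs=1e-12)
        assert pl["iridium"] == pytest.approx(0.060, abs=1e-12)

    def test_oblique_45_degree_chord(self, seed_6702):
        # 45 degrees through the axis: wall chords scale by sqrt(2)
        pl = ik.ray_path_lengths(seed_6702, ik.Ray([-1, 0, -1], [1, 0, 1]))
        assert pl["titanium"] == pytest.approx(0.010 * np.sqrt(2), abs=1e-9)

    @pytest.mark.parametrize("builder", [ik.build_6702, ik.build_flexisource])
    def test_matches_ray_marching_oracle(self, builder, rng):
        seed = builder()
        for _ in range(500):
            # aim near the seed so a good fraction of rays hit it
            target = rng.uniform(-0.4, 0.4, 3) * np.array([0.1, 0.1, 1.0])
            origin = rng.normal(0, 0.5, 3)
            origin /= max(np.linalg.norm(origin), 0.3)
            origin *= 0.8
            ray = ik.Ray(origin, target - origin)
            got = ik.ray_path_lengths(seed, ray)
            want = marching_path_lengths(seed, ray)
            for m in set(got) | set(want):
                assert got.get(m, 0.0) == pytest.approx(
                    want.get(m, 0.0), abs=5e-5), (m, origin, target)

    def test_rigid_translation_invariance(self, seed_flexi, rng):
        for _ in range(50):
            origin = rng.normal(0, 1, 3)
            direction = rng.normal(0, 1, 3)
            shift = rng.normal(0, 2, 3)
            a = ik.ray_path_lengths(seed_flexi, ik.Ray(origin, direction))
            b = ik.ray_path_lengths(seed_flexi,
                                    ik.Ray(origin + shift, direction),
                                    pose=shift)
            assert set(a) == set(b)
            for m in a:
                assert a[m] == pytest.approx(b[m], abs=1e-10)


class TestTransmission:
    def test_no_path_gives_unity(self, seed_6702):
        ray = ik.Ray([0, 1, 0], [0, 0, 1])
        assert ik.transmission_factor(seed_6702, ray, 30.0) == 1.0

    def test_half_value_layer(self):
        # a bare titanium slab-like seed: mu * t = ln 2 gives T = 1/2
        ti = get_material("titanium")
        e = 60.0
        t_half = np.log(2) / ti.mu(e)
        slab = ik.SeedModel("slab", "test", [
            __import__("isakernel.seeds", fromlist=["SeedComponent"])
            .SeedComponent(Cylinder(5.0, 0.0, t_half), "titanium")],
            envelope=[0], overall_length_cm=t_half, outer_diameter_cm=10.0,
            active_length_cm=1.0)
        T = ik.transmission_factor(slab, ik.Ray([0, 0, -1], [0, 0, 1]), e)
        assert T == pytest.approx(0.5, rel=1e-9)

    def test_stacked_seeds_multiply(self, seed_flexi):
        ray = ik.Ray([0, 0, 5], [0, 0, -1])
        e = 316.5
        t1 = ik.transmission_factor(seed_flexi, ray, e, pose=(0, 0, 2.0))
        t2 = ik.transmission_factor(seed_flexi, ray, e, pose=(0, 0, 0.0))
        both = t1 * t2
        # independent exponentials multiply
        tsum = (ik.transmission_factor(seed_flexi, ray, e, pose=(0, 0, 2.0))
                * ik.transmission_factor(seed_flexi, ray, e, pose=(0, 0, 0.0)))
        assert both == pytest.approx(tsum, rel=1e-14)
        assert 0 < both < t1 < 1

    def test_monotone_in_energy_attenuation(self, seed_6702):
        # lower photon energy -> larger mu -> smaller transmission
        ray = ik.Ray([-1, 0, 0], [1, 0, 0])
        t_lo = ik.transmission_factor(seed_6702, ray, 25.0)
        t_hi = ik.transmission_factor(seed_6702, ray, 35.0)
        assert t_lo < t_hi <= 1.0

    def test_energy_outside_tables_rejected(self, seed_6702):
        with pytest.raises(ValueError):
            ik.transmission_factor(seed_6702, ik.Ray([-1, 0, 0], [1, 0, 0]), 2.0)


class TestSegmentHits:
    def test_blocked_and_clear(self, seed_6702):
        starts = np.zeros((1, 3))
        assert segment_hits(seed_6702, [0, 0.5, 0.5], starts,
                            np.array([[0, 1.0, 1.0]]))[0]
        assert not segment_hits(seed_6702, [0, 0.5, -0.5], starts,
                                np.array([[0, 1.0, 1.0]]))[0]
        # dummy beyond the segment end does not block
        assert not segment_hits(seed_6702, [0, 2.0, 2.0], starts,
                                np.array([[0, 1.0, 1.0]]))[0]
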