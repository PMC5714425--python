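"""Parametric seed solid models and ray-seed path-length machinery.

A seed is an ordered list of convex components (cylinders, spheres,
hemispherical end welds, cone frusta) on a common axis (local +z, the tip
direction).  Nesting is resolved by construction: every component records
the material it is embedded in (``parent_material``), and because each
child shape lies strictly inside its parent, the net chord of material m
along a ray is

    len(m) = sum chords of components made of m  -  sum chords of components
             whose parent is m.

This makes path lengths and attenuation sums exact linear combinations of
per-component chords, which vectorizes over many rays at once.

Seeds in a scene are mutually parallel (translated poses only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .materials import MaterialSpec, get_material

__all__ = ["Ray", "Cylinder", "Sphere", "Hemisphere", "ConeFrustum",
           "SeedComponent", "SeedModel", "build_6702", "build_flexisource",
           "ray_path_lengths", "transmission_factor", "segment_hits"]

#: chords shorter than this are grazing tangencies and treated as misses (cm)
TANGENT_TOL_CM = 1e-7


@dataclass(frozen=True)
class Ray:
    """A half-line: origin plus unit direction, parametrized by t >= 0 (cm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("ray direction must be non-zero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    @classmethod
    def between(cls, a, b) -> tuple["Ray", float]:
        """Ray from a toward b and the distance |b - a|."""
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        return cls(a, b - a), float(np.linalg.norm(b - a))


# ---------------------------------------------------------------------------
# shapes (axisymmetric, in the seed local frame)

@dataclass(frozen=True)
class Cylinder:
    radius: float
    z0: float
    z1: float


@dataclass(frozen=True)
class Sphere:
    cz: float
    radius: float


@dataclass(frozen=True)
class Hemisphere:
    """Half ball: |x - (0,0,cz)| <= radius and sign*(z - cz) >= 0."""

    cz: float
    radius: float
    sign: int  # +1 caps toward +z, -1 toward -z


@dataclass(frozen=True)
class ConeFrustum:
    """Solid of revolution with radius linear in z between (z0, r0), (z1, r1)."""

    z0: float
    z1: float
    r0: float
    r1: float


def _slab_interval(oz, dz, z0, z1):
    """t-interval where z(t) in [z0, z1]; (lo, hi) arrays, lo > hi == miss."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (z0 - oz) / dz
        tb = (z1 - oz) / dz
    lo = np.minimum(ta, tb)
    hi = np.maximum(ta, tb)
    par = np.abs(dz) < 1e-15
    inside = (oz >= z0) & (oz <= z1)
    lo = np.where(par, np.where(inside, -np.inf, np.inf), lo)
    hi = np.where(par, np.where(inside, np.inf, -np.inf), hi)
    return lo, hi


def _quad_interval(A, B, C):
    """Interval where A t^2 + B t + C <= 0, for A > 0 branches; A ~ 0 linear."""
    disc = B * B - 4 * A * C
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(np.maximum(disc, 0.0))
        lo = (-B - sq) / (2 * A)
        hi = (-B + sq) / (2 * A)
        tlin = -C / B
    miss = disc <= 0
    lin = np.abs(A) < 1e-18
    # linear case: B t + C <= 0
    lin_pos = lin & (np.abs(B) >= 1e-18)
    lo = np.where(lin_pos, np.where(B > 0, -np.inf, tlin), lo)
    hi = np.where(lin_pos, np.where(B > 0, tlin, np.inf), hi)
    const = lin & (np.abs(B) < 1e-18)
    lo = np.where(const, np.where(C <= 0, -np.inf, np.inf), lo)
    hi = np.where(const, np.where(C <= 0, np.inf, -np.inf), hi)
    miss = miss & ~lin
    lo = np.where(miss, np.inf, lo)
    hi = np.where(miss, -np.inf, hi)
    return lo, hi


def shape_interval(shape, o: np.ndarray, d: np.ndarray):
    """(lo, hi) ray-parameter interval inside ``shape``.

    ``o``/``d`` are (N, 3); direction rows must be unit so t is in cm.
    Misses are encoded as lo > hi.
    """
    ox, oy, oz = o[:, 0], o[:, 1], o[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    if isinstance(shape, Cylinder):
        A = dx * dx + dy * dy
        B = 2 * (ox * dx + oy * dy)
        C = ox * ox + oy * oy - shape.radius**2
        lo, hi = _quad_interval(A, B, C)
        slo, shi = _slab_interval(oz, dz, shape.z0, shape.z1)
        return np.maximum(lo, slo), np.minimum(hi, shi)
    if isinstance(shape, Sphere):
        cz = shape.cz
        B = 2 * (ox * dx + oy * dy + (oz - cz) * dz)
        C = ox * ox + oy * oy + (oz - cz) ** 2 - shape.radius**2
        return _quad_interval(np.ones_like(B), B, C)
    if isinstance(shape, Hemisphere):
        lo, hi = shape_interval(Sphere(shape.cz, shape.radius), o, d)
        # half-space sign*(z - cz) >= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            tstar = (shape.cz - oz) / dz
        going_up = dz * shape.sign > 0
        par = np.abs(dz) < 1e-15
        h_lo = np.where(going_up, tstar, -np.inf)
        h_hi = np.where(going_up, np.inf, tstar)
        inside0 = shape.sign * (oz - shape.cz) >= 0
        h_lo = np.where(par, np.where(inside0, -np.inf, np.inf), h_lo)
        h_hi = np.where(par, np.where(inside0, np.inf, -np.inf), h_hi)
        return np.maximum(lo, h_lo), np.minimum(hi, h_hi)
    if isinstance(shape, ConeFrustum):
        k = (shape.r1 - shape.r0) / (shape.z1 - shape.z0)
        m = shape.r0 + k * (oz - shape.z0)  # cone radius at ray origin's z
        A = dx * dx + dy * dy - (k * dz) ** 2
        B = 2 * (ox * dx + oy * dy - k * dz * m)
        C = ox * ox + oy * oy - m * m
        slo, shi = _slab_interval(oz, dz, min(shape.z0, shape.z1),
                                  max(shape.z0, shape.z1))
        # Candidate boundaries: slab faces and cone-surface roots; the region
        # inside a convex frustum along a line is a single interval, so test
        # midpoints of candidate sub-intervals for membership.
        disc = B * B - 4 * A * C
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            q0 = (-B - sq) / (2 * A)
            q1 = (-B + sq) / (2 * A)
            tlin = -C / B
        lin = np.abs(A) < 1e-18
        q0 = np.where(lin, tlin, q0)
        q1 = np.where(lin, tlin, q1)
        bad = ~np.isfinite(q0) | (disc < 0)
        q0 = np.where(bad, slo, np.clip(q0, slo, shi))
        q1 = np.where(bad, slo, np.clip(q1, slo, shi))
        ts = np.sort(np.stack([slo, np.minimum(q0, q1), np.maximum(q0, q1), shi]),
                     axis=0)

        def inside(t):
            x = ox + t * dx
            y = oy + t * dy
            z = oz + t * dz
            rad = shape.r0 + k * (z - shape.z0)
            return (x * x + y * y <= rad * rad)

        lo = np.full_like(ox, np.inf)
        hi = np.full_like(ox, -np.inf)
        valid_slab = slo <= shi
        for i in range(3):
            a, b = ts[i], ts[i + 1]
            seg_ok = valid_slab & np.isfinite(a) & np.isfinite(b) & (b > a)
            mid = 0.5 * (np.where(seg_ok, a, 0.0) + np.where(seg_ok, b, 0.0))
            good = seg_ok & inside(mid)
            lo = np.where(good & (a < lo), a, lo)
            hi = np.where(good & (b > hi), b, hi)
        return lo, hi
    raise TypeError(f"unsupported shape {type(shape).__name__}")


# ---------------------------------------------------------------------------
# seed models

@dataclass(frozen=True)
class SeedComponent:
    shape: object
    material: str
    parent_material: str | None = None  # None == the surrounding medium


@dataclass
class SeedModel:
    """A physical seed: nested components plus its active-region descriptor.

    ``envelope`` lists the indices of the outer-surface components (used by
    the line-of-sight shadow test).  ``emission_shapes`` describe where
    photons originate for transport; ``active_length_cm`` is the TG-43
    effective line length used for dose queries.
    """

    name: str
    radionuclide: str
    components: list[SeedComponent]
    envelope: list[int]
    overall_length_cm: float
    outer_diameter_cm: float
    active_length_cm: float
    emission_shapes: list[object] = field(default_factory=list)

    def materials(self) -> set[str]:
        return {c.material for c in self.components}

    def to_json(self, path) -> None:
        def enc(s):
            return {"type": type(s).__name__,
                    **{k: getattr(s, k) for k in s.__dataclass_fields__}}

        obj = {"name": self.name, "radionuclide": self.radionuclide,
               "overall_length_cm": self.overall_length_cm,
               "outer_diameter_cm": self.outer_diameter_cm,
               "active_length_cm": self.active_length_cm,
               "envelope": self.envelope,
               "components": [{"shape": enc(c.shape), "material": c.material,
                               "parent_material": c.parent_material}
                              for c in self.components],
               "emission_shapes": [enc(s) for s in self.emission_shapes]}
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path) -> "SeedModel":
        obj = json.loads(Path(path).read_text())
        kinds = {"Cylinder": Cylinder, "Sphere": Sphere,
                 "Hemisphere": Hemisphere, "ConeFrustum": ConeFrustum}

        def dec(s):
            kw = dict(s)
            return kinds[kw.pop("type")](**kw)

        comps = [SeedComponent(dec(c["shape"]), c["material"],
                               c.get("parent_material"))
                 for c in obj["components"]]
        return cls(obj["name"], obj["radionuclide"], comps, obj["envelope"],
                   obj["overall_length_cm"], obj["outer_diameter_cm"],
                   obj["active_length_cm"],
                   [dec(s) for s in obj.get("emission_shapes", [])])


def build_6702() -> SeedModel:
    """Amersham model 6702 I-125 seed.

    Three 0.600 mm resin spheres at 1.10 mm pitch inside a titanium tube
    (0.800 mm OD, 0.050 mm wall); each end weld is read as a 0.400 mm-radius
    hemisphere on a 0.100 mm solid cylinder (0.500 mm per end); overall
    length 4.60 mm, effective active length 3.30 mm.  The I-125 coating has
    negligible thickness and is not modeled.
    """
    r_out, wall = 0.040, 0.0050
    tube_half = 0.18  # 3.6 mm central tube
    comps = [
        SeedComponent(Cylinder(r_out, -tube_half, tube_half), "titanium"),
        SeedComponent(Cylinder(r_out - wall, -tube_half, tube_half),
                      "vacuum", parent_material="titanium"),
        SeedComponent(Sphere(-0.110, 0.030), "resin", parent_material="vacuum"),
        SeedComponent(Sphere(0.0, 0.030), "resin", parent_material="vacuum"),
        SeedComponent(Sphere(0.110, 0.030), "resin", parent_material="vacuum"),
        SeedComponent(Cylinder(r_out, tube_half, tube_half + 0.010), "titanium"),
        SeedComponent(Hemisphere(tube_half + 0.010, r_out, +1), "titanium"),
        SeedComponent(Cylinder(r_out, -tube_half - 0.010, -tube_half), "titanium"),
        SeedComponent(Hemisphere(-tube_half - 0.010, r_out, -1), "titanium"),
    ]
    return SeedModel(
        name="6702", radionuclide="I125_6702", components=comps,
        envelope=[0, 5, 6, 7, 8],
        overall_length_cm=0.460, outer_diameter_cm=0.080,
        active_length_cm=0.330,
        emission_shapes=[Sphere(-0.110, 0.030), Sphere(0.0, 0.030),
                         Sphere(0.110, 0.030)])


def build_flexisource() -> SeedModel:
    """Ir-192 Flexisource seed (used here as an LDR stand-in).

    3.50 x 0.60 mm iridium core (22.42 g/cm^3) inside an AISI 304 steel
    capsule, 0.85 mm OD and 4.60 mm total length, with a 23.6 deg half-angle
    conical tip (face radius 0.17 mm) and a 5.0 x 0.5 mm steel cable.  The
    hollow section (inner radius 0.335 mm, length 3.60 mm) is centered on
    the core; residual axial budget forms the solid front/rear sections.
    """
    r_out = 0.0425
    tip_len = (r_out - 0.017) / np.tan(np.radians(23.6))  # 0.0584 cm
    z_tip0 = 0.20                      # start of conical tip
    z_back = z_tip0 + tip_len - 0.46   # capsule rear face (-0.2016)
    comps = [
        SeedComponent(Cylinder(r_out, z_back, z_tip0), "steel304"),
        SeedComponent(ConeFrustum(z_tip0, z_tip0 + tip_len, r_out, 0.017),
                      "steel304"),
        SeedComponent(Cylinder(0.0335, -0.18, 0.18),
                      "vacuum", parent_material="steel304"),
        SeedComponent(Cylinder(0.030, -0.175, 0.175),
                      "iridium", parent_material="vacuum"),
        SeedComponent(Cylinder(0.025, z_back - 0.50, z_back), "steel304"),
    ]
    return SeedModel(
        name="Flexisource", radionuclide="Ir192_Flexisource", components=comps,
        envelope=[0, 1, 4],
        overall_length_cm=0.460, outer_diameter_cm=0.085,
        active_length_cm=0.350,
        emission_shapes=[Cylinder(0.030, -0.175, 0.175)])


# ---------------------------------------------------------------------------
# path lengths and attenuation

def component_chords(seed: SeedModel, pose, origins: np.ndarray,
                     directions: np.ndarray, t_max) -> np.ndarray:
    """Per-component chord lengths (n_components, N) along rays clipped to
    t in [0, t_max].  ``pose`` is the seed center in world coordinates."""
    pose = np.asarray(pose, float)
    o = np.atleast_2d(origins) - pose[None, :]
    d = np.atleast_2d(directions)
    tm = np.broadcast_to(np.asarray(t_max, float), (o.shape[0],))
    out = np.zeros((len(seed.components), o.shape[0]))
    for i, comp in enumerate(seed.components):
        lo, hi = shape_interval(comp.shape, o, d)
        lo = np.maximum(lo, 0.0)
        hi = np.minimum(hi, tm)
        chord = np.maximum(hi - lo, 0.0)
        chord[chord < TANGENT_TOL_CM] = 0.0
        out[i] = chord
    return out


def ray_path_lengths(seed: SeedModel, ray: Ray, pose=(0.0, 0.0, 0.0),
                     t_max: float = np.inf) -> dict[str, float]:
    """Chord length of the ray inside each material of the seed.

    Nested components are resolved innermost-first (a resin sphere claims
    the space carved out of the capsule interior).  Materials with zero net
    chord are omitted; a ray missing the seed returns an empty map.
    """
    chords = component_chords(seed, pose, ray.origin[None, :],
                              ray.direction[None, :], t_max)[:, 0]
    lengths: dict[str, float] = {}
    for comp, c in zip(seed.components, chords):
        if c <= 0:
            continue
        lengths[comp.material] = lengths.get(comp.material, 0.0) + c
        if comp.parent_material is not None:
            lengths[comp.parent_material] = (
                lengths.get(comp.parent_material, 0.0) - c)
    return {m: v for m, v in lengths.items()
            if v > TANGENT_TOL_CM and m != "vacuum"}


def transmission_factor(seed: SeedModel, ray: Ray, energy_keV: float,
                        pose=(0.0, 0.0, 0.0), t_max: float = np.inf,
                        medium: MaterialSpec | None = None) -> float:
    """Narrow-beam primary transmission exp(-sum mu(E) * t) through the seed.

    With ``medium`` given (e.g. water), each material chord contributes
    ``(mu_material - mu_medium) * t`` -- the attenuation *in excess of* the
    displaced medium, which is the quantity entering P-value estimates.
    """
    mu_medium = medium.mu(energy_keV) if medium is not None else 0.0
    chords = component_chords(seed, pose, ray.origin[None, :],
                              ray.direction[None, :], t_max)[:, 0]
    total = 0.0
    for comp, c in zip(seed.components, chords):
        if c <= 0:
            continue
        mu_c = get_material(comp.material).mu(energy_keV)
        mu_p = (get_material(comp.parent_material).mu(energy_keV)
                if comp.parent_material is not None else mu_medium)
        total += (mu_c - mu_p) * c
    return float(np.exp(-total))


def segment_hits(seed: SeedModel, pose, starts: np.ndarray,
                 ends: np.ndarray) -> np.ndarray:
    """Vectorized: does segment start->end intersect the seed's outer
    envelope?  Returns a boolean array of length N."""
    starts = np.atleast_2d(np.asarray(starts, float))
    ends = np.atleast_2d(np.asarray(ends, float))
    starts, ends = np.broadcast_arrays(starts, ends)
    delta = ends - starts
    dist = np.linalg.norm(delta, axis=1)
    safe = np.maximum(dist, 1e-300)
    dirs = delta / safe[:, None]
    pose = np.asarray(pose, float)
    o = starts - pose[None, :]
    hit = np.zeros(len(starts), dtype=bool)
    for idx in seed.envelope:
        lo, hi = shape_interval(seed.components[idx].shape, o, dirs)
        lo = np.maximum(lo, 0.0)
        hi = np.minimum(hi, dist)
        hit |= (hi - lo) > TANGENT_TOL_CM
    return hit


def build_seed(radionuclide: str) -> SeedModel:
    """Seed model for a packaged radionuclide key."""
    if radionuclide == "I125_6702":
        return build_6702()
    if radionuclide == "Ir192_Flexisource":
        return build_flexisource()
    raise KeyError(f"no seed model for radionuclide {radionuclide!r}")
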