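"""Desk-scale photon transport: analytic primary kernels and a minimal
Monte Carlo (photoelectric + Klein-Nishina Compton, track-length kerma
tally) that generates P-kernels and serves as the full-simulation oracle.

Physics scope is deliberately small: no Rayleigh scattering, no binding
corrections or characteristic x-rays, no electron/beta transport; photons
below a 5 keV cutoff are absorbed.  The phantom is a full scattering water
sphere (radius 40 cm by default).  History counts are meant for desk-scale
property checks, orders of magnitude below production Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import _mc
from .grid import DoseGrid, standard_grid
from .isa import PKernel
from .materials import MaterialSpec, get_material
from .seeds import (SeedModel, component_chords, segment_hits)

__all__ = ["Spectrum", "TransportConfig", "SceneSeed", "run_transport",
           "estimate_pvalues", "analytic_kernel", "PValueEstimate",
           "load_spectrum"]

_E_LOG_GRID = np.exp(np.linspace(np.log(5.0), np.log(1000.0), 96))

_SPECTRUM_FILES = {"I125_6702": "i125.csv", "Ir192_Flexisource": "ir192.csv"}


@dataclass(frozen=True)
class Spectrum:
    """A discrete photon line spectrum (energies keV, intensities per decay)."""

    energies_keV: np.ndarray
    intensities: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, float)
        w = np.asarray(self.intensities, float)
        if e.size == 0 or np.any(w <= 0):
            raise ValueError("spectrum needs at least one line with positive intensity")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "intensities", w)

    @property
    def mean_energy_keV(self) -> float:
        """Intensity-weighted mean photon energy."""
        return float(np.sum(self.energies_keV * self.intensities)
                     / np.sum(self.intensities))

    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.intensities)
        return c / c[-1]


def load_spectrum(radionuclide: str) -> Spectrum:
    if radionuclide not in _SPECTRUM_FILES:
        raise KeyError(f"no packaged spectrum for {radionuclide!r}")
    ref = resources.files("isakernel.data.spectra") / _SPECTRUM_FILES[radionuclide]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    return Spectrum(df["energy_keV"].to_numpy(float),
                    df["intensity"].to_numpy(float), name=radionuclide)


@dataclass
class TransportConfig:
    n_histories: int
    rng_seed: int = 0
    phantom_radius_cm: float = 40.0
    water_density_g_cm3: float = 0.998
    physics: str = "compton_pe"   # or "primary_only"
    cutoff_keV: float = 5.0

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.water_density_g_cm3 <= 0 or self.phantom_radius_cm <= 0:
            raise ValueError("densities and radii must be positive")
        if self.physics not in ("primary_only", "compton_pe"):
            raise ValueError("physics must be 'primary_only' or 'compton_pe'")


def point_source_model(name: str = "point") -> SeedModel:
    """A bare, unencapsulated point-like emitter (no attenuating parts).

    Useful for transport sanity checks against closed-form narrow-beam
    formulas where capsule self-attenuation must be absent.
    """
    from .seeds import Sphere

    return SeedModel(name=name, radionuclide=name, components=[],
                     envelope=[], overall_length_cm=0.0,
                     outer_diameter_cm=0.0, active_length_cm=1e-6,
                     emission_shapes=[Sphere(0.0, 1e-6)])


@dataclass(frozen=True)
class SceneSeed:
    id: str
    model: SeedModel
    position_cm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position_cm",
                           np.asarray(self.position_cm, float))


# ---------------------------------------------------------------------------
# scene compilation

_N_E = 96
_R_E2 = 7.94078e-26
_N_A = 6.02214e23
_WATER_Z_A = 0.5551


def _kn_sigma(e_kev: np.ndarray) -> np.ndarray:
    a = np.asarray(e_kev, float) / 510.999
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * _R_E2 * (t1 + t2 + t3)


def _compile_components(scene: list[SceneSeed]):
    from .seeds import Cylinder, Sphere, Hemisphere, ConeFrustum

    kinds, pars, mats, parents = [], [], [], []
    mat_names: list[str] = []

    def mat_index(name: str | None) -> int:
        if name is None:
            return -1
        if name not in mat_names:
            mat_names.append(name)
        return mat_names.index(name)

    for seed in scene:
        px, py, pz = seed.position_cm
        for comp in seed.model.components:
            s = comp.shape
            if isinstance(s, Cylinder):
                kinds.append(_mc.CYL)
                pars.append([px, py, s.radius, s.z0 + pz, s.z1 + pz, 0.0])
            elif isinstance(s, Sphere):
                kinds.append(_mc.SPH)
                pars.append([px, py, s.cz + pz, s.radius, 0.0, 0.0])
            elif isinstance(s, Hemisphere):
                kinds.append(_mc.HEMI)
                pars.append([px, py, s.cz + pz, s.radius, float(s.sign), 0.0])
            elif isinstance(s, ConeFrustum):
                kinds.append(_mc.FRUSTUM)
                pars.append([px, py, s.z0 + pz, s.z1 + pz, s.r0, s.r1])
            else:
                raise TypeError(f"unsupported shape {type(s).__name__}")
            mats.append(mat_index(comp.material))
            parents.append(mat_index(comp.parent_material))
    kinds = np.array(kinds, dtype=np.int64) if kinds else np.zeros(0, np.int64)
    pars = (np.array(pars, dtype=float) if len(pars)
            else np.zeros((0, 6)))
    return (kinds, pars, np.array(mats, np.int64), np.array(parents, np.int64),
            mat_names)


def _mu_tables(mat_names: list[str], water_density: float):
    e = _E_LOG_GRID
    mu_log = np.zeros((max(len(mat_names), 1), e.size))
    for i, name in enumerate(mat_names):
        m = get_material(name)
        mu_log[i] = np.log(np.maximum(m.mass_attenuation(e) * m.density, 1e-30))
    water = get_material("water")
    mu_w = water.mass_attenuation(e) * water_density
    mu_w_log = np.log(mu_w)
    muen_w = water.mass_energy_absorption(e)
    n_e = water_density * _N_A * _WATER_Z_A
    fc = np.clip(_kn_sigma(e) * n_e / mu_w, 0.0, 1.0)
    log_e0 = np.log(e[0])
    dlog = np.log(e[1]) - np.log(e[0])
    return mu_log, mu_w_log, muen_w, fc, log_e0, dlog


def _compile_emission(active: SceneSeed):
    from .seeds import Cylinder, Sphere

    kinds, pars, weights = [], [], []
    px, py, pz = active.position_cm
    shapes = active.model.emission_shapes
    if not shapes:
        raise ValueError(f"seed model {active.model.name!r} has no active region")
    for s in shapes:
        if isinstance(s, Sphere):
            kinds.append(0)
            pars.append([px, py, s.cz + pz, s.radius, 0.0])
            weights.append(4.0 / 3.0 * np.pi * s.radius**3)
        elif isinstance(s, Cylinder):
            kinds.append(1)
            pars.append([px, py, s.z0 + pz, s.z1 + pz, s.radius])
            weights.append(np.pi * s.radius**2 * (s.z1 - s.z0))
        else:
            raise TypeError("emission shapes must be spheres or cylinders")
    cum = np.cumsum(weights)
    return (np.array(kinds, np.int64), np.array(pars, float), cum / cum[-1])


def run_transport(scene: list[SceneSeed], active_id: str, spectrum: Spectrum,
                  config: TransportConfig,
                  grid: DoseGrid | None = None,
                  require_cover: bool = True) -> DoseGrid:
    """Monte Carlo kerma grid (MeV/g per history) for one active seed.

    All seeds in ``scene`` (including the active one) attenuate; only the
    active seed emits.  Bit-identical results for a fixed ``rng_seed``.
    """
    grid = grid if grid is not None else standard_grid()
    lo, hi = grid.bounds()
    for s in scene:
        if require_cover and (np.any(s.position_cm < lo)
                              or np.any(s.position_cm > hi)):
            raise ValueError(f"seed {s.id!r} at {s.position_cm} lies outside "
                             "the tally grid (pass require_cover=False for "
                             "off-scene tally windows)")
        if np.linalg.norm(s.position_cm) > config.phantom_radius_cm:
            raise ValueError(f"seed {s.id!r} lies outside the phantom")
    active = next((s for s in scene if s.id == active_id), None)
    if active is None:
        raise KeyError(f"active seed {active_id!r} not in scene")
    emin, emax = spectrum.energies_keV.min(), spectrum.energies_keV.max()
    if emin < _E_LOG_GRID[0] or emax > _E_LOG_GRID[-1]:
        raise ValueError("spectrum energies outside cross-section table range")

    kinds, pars, mats, parents, mat_names = _compile_components(scene)
    mu_log, mu_w_log, muen_w, fc, log_e0, dlog = _mu_tables(
        mat_names, config.water_density_g_cm3)
    ekinds, epars, ecum = _compile_emission(active)
    tally = np.zeros(grid.shape)
    physics = (_mc.PRIMARY_ONLY if config.physics == "primary_only"
               else _mc.COMPTON_PE)
    _mc.run_histories(
        config.n_histories, config.rng_seed,
        ekinds, epars, ecum,
        spectrum.energies_keV.astype(float), spectrum.cdf(),
        kinds, pars, mats, parents,
        log_e0, dlog, mu_log, muen_w, fc, mu_w_log,
        grid.origin_cm.astype(float), float(grid.voxel_cm),
        grid.shape[0], grid.shape[1], grid.shape[2],
        float(config.phantom_radius_cm), physics, float(config.cutoff_keV),
        tally)
    out = grid.copy_empty()
    out.values = tally / (config.n_histories * grid.voxel_cm**3)
    out.units = "MeV/g per history"
    return out


def transport_energy_balance(scene, active_id, spectrum, config,
                             grid=None) -> tuple[float, float]:
    """(mean emitted energy, mean in-grid deposited kerma estimate) per
    history, in MeV -- deposition can never exceed emission."""
    grid = grid if grid is not None else standard_grid()
    kinds, pars, mats, parents, mat_names = _compile_components(scene)
    mu_log, mu_w_log, muen_w, fc, log_e0, dlog = _mu_tables(
        mat_names, config.water_density_g_cm3)
    active = next(s for s in scene if s.id == active_id)
    ekinds, epars, ecum = _compile_emission(active)
    tally = np.zeros(grid.shape)
    physics = (_mc.PRIMARY_ONLY if config.physics == "primary_only"
               else _mc.COMPTON_PE)
    emitted, deposited = _mc.run_histories(
        config.n_histories, config.rng_seed, ekinds, epars, ecum,
        spectrum.energies_keV.astype(float), spectrum.cdf(),
        kinds, pars, mats, parents,
        log_e0, dlog, mu_log, muen_w, fc, mu_w_log,
        grid.origin_cm.astype(float), float(grid.voxel_cm),
        grid.shape[0], grid.shape[1], grid.shape[2],
        float(config.phantom_radius_cm), physics, float(config.cutoff_keV),
        tally)
    n = config.n_histories
    # deposited carries (mu_en/rho * chord) weighting: an upper bound on the
    # energy left in the grid, in keV -> convert both to MeV
    return emitted / n / 1000.0, deposited / n / 1000.0


@dataclass
class PValueEstimate:
    """Voxelwise P with a per-voxel standard error from batch statistics.

    Voxels with zero baseline dose are undefined (NaN) and flagged.
    """

    p: DoseGrid
    se: DoseGrid
    undefined: np.ndarray

    def value_at(self, point) -> float:
        return self.p.value_at(point)

    def se_at(self, point) -> float:
        return self.se.value_at(point)

    def to_kernel(self, radionuclide: str, dummy_offset_cm) -> PKernel:
        return PKernel(radionuclide, np.asarray(dummy_offset_cm, float), self.p)


def estimate_pvalues(scene: list[SceneSeed], active_id: str,
                     spectrum: Spectrum, config: TransportConfig,
                     grid: DoseGrid | None = None,
                     baseline: list[SceneSeed] | None = None,
                     n_batches: int = 10,
                     require_cover: bool = True) -> PValueEstimate:
    """Voxelwise perturbation factors P = D(scene) / D(baseline).

    ``baseline`` defaults to the active seed alone.  Numerator and
    denominator of each batch share one RNG seed (common random numbers):
    trajectories are identical and only the seed-attenuation weights differ,
    so the ratio variance is strongly suppressed.  The standard error is the
    spread of per-batch ratios.
    """
    grid = grid if grid is not None else standard_grid()
    if baseline is None:
        baseline = [s for s in scene if s.id == active_id]
    if config.n_histories < n_batches:
        raise ValueError("need at least one history per batch")
    per = config.n_histories // n_batches
    num_sum = np.zeros(grid.shape)
    den_sum = np.zeros(grid.shape)
    ratios = []
    for b in range(n_batches):
        sub = TransportConfig(per, rng_seed=config.rng_seed + b,
                              phantom_radius_cm=config.phantom_radius_cm,
                              water_density_g_cm3=config.water_density_g_cm3,
                              physics=config.physics,
                              cutoff_keV=config.cutoff_keV)
        num = run_transport(scene, active_id, spectrum, sub, grid,
                            require_cover=require_cover).values
        den = run_transport(baseline, active_id, spectrum, sub, grid,
                            require_cover=require_cover).values
        num_sum += num
        den_sum += den
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios.append(np.where(den > 0, num / den, np.nan))
    ratios = np.array(ratios)
    undefined = den_sum <= 0
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        p_vals = np.where(undefined, np.nan, num_sum / den_sum)
        se_vals = (np.nanstd(ratios, axis=0, ddof=1)
                   / np.sqrt(np.sum(np.isfinite(ratios), axis=0).clip(min=1)))
    p = grid.copy_empty()
    p.values = p_vals
    p.units = "P"
    se = grid.copy_empty()
    se.values = se_vals
    se.units = "P"
    return PValueEstimate(p, se, undefined)


def analytic_kernel(active: SeedModel, dummy: SeedModel, dummy_offset_cm,
                    spectrum: Spectrum, grid: DoseGrid | None = None,
                    medium: MaterialSpec | None = None,
                    n_source_samples: int = 1,
                    rng_seed: int = 0) -> PKernel:
    """Primary-beam perturbation kernel: for each voxel,

        P = sum_lines w(E) * T(E) / sum_lines w(E),

    where T is the narrow-beam transmission through the dummy along the
    source-to-voxel-center ray, averaged over ``n_source_samples`` emission
    points of the active region (the first sample is the center).  Voxels
    whose rays all miss the dummy get exactly P = 1.  With ``medium`` given,
    transmission counts attenuation in excess of the displaced medium --
    the convention that matches Monte Carlo P-value estimates in water.
    """
    grid = grid if grid is not None else standard_grid()
    offset = np.asarray(dummy_offset_cm, float)
    radial = np.hypot(offset[0], offset[1])
    if (radial < (active.outer_diameter_cm + dummy.outer_diameter_cm) / 2
            and abs(offset[2]) < (active.overall_length_cm
                                  + dummy.overall_length_cm) / 2):
        raise ValueError("dummy seed overlaps the active seed")

    sources = [np.zeros(3)]
    if n_source_samples > 1:
        rng = np.random.default_rng(rng_seed)
        sources += _sample_active_points(active, n_source_samples - 1, rng)

    centers = grid.centers()
    mu_medium = (medium.mu(spectrum.energies_keV) if medium is not None
                 else np.zeros(len(spectrum.energies_keV)))
    mats = [get_material(c.material) for c in dummy.components]
    parents = [get_material(c.parent_material) if c.parent_material is not None
               else None for c in dummy.components]

    acc = np.zeros(len(centers))
    hit_any = np.zeros(len(centers), dtype=bool)
    wsum = float(np.sum(spectrum.intensities))
    for src in sources:
        delta = centers - src[None, :]
        dist = np.linalg.norm(delta, axis=1)
        safe = np.maximum(dist, 1e-12)
        dirs = delta / safe[:, None]
        chords = component_chords(dummy, offset, np.broadcast_to(src, centers.shape),
                                  dirs, dist)
        hit_any |= segment_hits(dummy, offset,
                                np.broadcast_to(src, centers.shape), centers)
        t_sum = np.zeros(len(centers))
        for e_idx, (e, w) in enumerate(zip(spectrum.energies_keV,
                                           spectrum.intensities)):
            tau = np.zeros(len(centers))
            for ci, comp in enumerate(dummy.components):
                mu_c = mats[ci].mu(e)
                mu_p = (parents[ci].mu(e) if parents[ci] is not None
                        else float(np.atleast_1d(mu_medium)[e_idx]))
                tau += (mu_c - mu_p) * chords[ci]
            t_sum += w * np.exp(-tau)
        acc += t_sum / wsum
    p_vals = acc / len(sources)
    p_vals[~hit_any] = 1.0
    p_vals = np.minimum(p_vals, 1.0 + 0.0)  # primary-only kernels never exceed 1
    out = grid.copy_empty()
    out.values = p_vals.reshape(grid.shape)
    out.units = "P"
    return PKernel(active.radionuclide, offset, out)


def _sample_active_points(model: SeedModel, n: int, rng) -> list[np.ndarray]:
    """Uniform samples over the active-region shapes (volume-weighted)."""
    from .seeds import Cylinder, Sphere

    shapes = model.emission_shapes
    vols = []
    for s in shapes:
        if isinstance(s, Sphere):
            vols.append(4 / 3 * np.pi * s.radius**3)
        elif isinstance(s, Cylinder):
            vols.append(np.pi * s.radius**2 * (s.z1 - s.z0))
        else:
            raise TypeError("emission shapes must be spheres or cylinders")
    probs = np.array(vols) / np.sum(vols)
    out = []
    for _ in range(n):
        s = shapes[rng.choice(len(shapes), p=probs)]
        if isinstance(s, Sphere):
            while True:
                v = rng.uniform(-1, 1, 3)
                if v @ v <= 1:
                    break
            out.append(np.array([0.0, 0.0, s.cz]) + s.radius * v)
        else:
            while True:
                v = rng.uniform(-1, 1, 2)
                if v @ v <= 1:
                    break
            z = rng.uniform(s.z0, s.z1)
            out.append(np.array([s.radius * v[0], s.radius * v[1], z]))
    return out
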