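"""The interseed-attenuation (ISA) perturbation model.

For each seed of a multi-seed implant taken as *active*, every other
(inactive, "dummy") seed perturbs the active seed's dose at a point by a
factor P <= 1 -- the ratio of dose with the dummy present to dose without
it.  The model combines precomputed single-dummy kernels multiplicatively:

    P_MODEL = P_1 * P_2 * ... * P_N,      ISA = 1 - P_MODEL

and a dummy contributes P < 1 only if it blocks the straight line from the
active source to the calculation point (the shadow rule); every other dummy
contributes exactly 1.

Kernels are gridded P(voxel) fields for one relative active/dummy
placement, indexed on the 0.25 cm lattice out to 6 cm separation, with
mirror/azimuthal symmetry exploited so only one quadrant is stored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import DoseGrid
from .plan import ImplantPlan, KERNEL_COVERAGE_CM
from .seeds import SeedModel, build_seed, segment_hits
from .tg43 import TG43Params, superpose

__all__ = ["PKernel", "KernelBank", "MissingKernelError", "shadow_test",
           "lookup_p", "combine_pvalues", "isa_value", "p_model_at",
           "corrected_dose"]

#: P-values may exceed 1 slightly through scatter excess / MC statistics
SCATTER_EPS = 0.02
#: lattice pitch for kernel indexing (cm) and allowed off-lattice slack
LATTICE_CM = 0.25
OFF_LATTICE_TOL_CM = 0.05


class MissingKernelError(KeyError):
    """No kernel covers the requested active/dummy relative placement."""


def combine_pvalues(p_list) -> float:
    """Product of single-dummy perturbation factors (empty product = 1).

    Each factor must lie in (0, 1 + eps] with eps = 0.02 for scatter excess.
    Commutative and associative by construction.
    """
    factors = [float(p) for p in p_list]
    for p in factors:
        if not (0.0 < p <= 1.0 + SCATTER_EPS):
            raise ValueError(f"P-value {p} outside (0, {1 + SCATTER_EPS}]")
    out = 1.0
    for p in sorted(factors):  # canonical order: exactly permutation-invariant
        out *= p
    return out


def isa_value(p_model: float) -> float:
    """Interseed-attenuation value ISA = 1 - P."""
    if not (0.0 < p_model <= 1.0 + SCATTER_EPS):
        raise ValueError(f"P_MODEL {p_model} outside (0, {1 + SCATTER_EPS}]")
    return 1.0 - p_model


def shadow_test(active_pos, dummy_model: SeedModel, dummy_pos, point,
                source_points=None) -> bool:
    """Does the line of sight from the active source to ``point`` cross the
    dummy seed's outer envelope?

    By default the segment starts at the active source's center; passing
    ``source_points`` (absolute coordinates sampled over the active region)
    widens the test to finite-source lines of sight (true if any is blocked).
    """
    point = np.asarray(point, float)
    starts = (np.atleast_2d(source_points) if source_points is not None
              else np.asarray(active_pos, float)[None, :])
    if np.allclose(point, np.asarray(active_pos, float)):
        raise ValueError("calculation point coincides with the active source")
    return bool(np.any(segment_hits(dummy_model, dummy_pos, starts,
                                    point[None, :])))


def shadow_mask(active_pos, dummy_model: SeedModel, dummy_pos,
                points: np.ndarray) -> np.ndarray:
    """Vectorized center-ray shadow test over (N, 3) points."""
    starts = np.broadcast_to(np.asarray(active_pos, float), points.shape)
    return segment_hits(dummy_model, dummy_pos, starts, points)


# ---------------------------------------------------------------------------
# kernels

@dataclass
class PKernel:
    """Gridded perturbation factors for one relative dummy placement.

    The grid lives in the active seed's frame (active center at the origin);
    ``dummy_offset_cm`` is the dummy center in that frame, on the x=0 plane
    with non-negative R and Z (other placements are reached by symmetry).
    """

    radionuclide: str
    dummy_offset_cm: np.ndarray
    grid: DoseGrid

    def __post_init__(self) -> None:
        self.dummy_offset_cm = np.asarray(self.dummy_offset_cm, float)
        vals = self.grid.values
        finite = vals[np.isfinite(vals)]
        if finite.size and (np.any(finite <= 0)
                            or np.any(finite > 1 + SCATTER_EPS)):
            raise ValueError("kernel P-values must lie in (0, 1 + eps]")

    def clamp(self) -> "PKernel":
        """Clamp scatter-excess values above 1 down to exactly 1 (explicit
        request only; printed-table round trips keep values untouched)."""
        g = self.grid.copy_empty()
        g.values = np.minimum(self.grid.values, 1.0)
        return PKernel(self.radionuclide, self.dummy_offset_cm.copy(), g)


def _lattice_key(value: float) -> int:
    k = round(value / LATTICE_CM)
    if abs(value - k * LATTICE_CM) > OFF_LATTICE_TOL_CM:
        raise MissingKernelError(
            f"offset {value:.3f} cm is off the {LATTICE_CM} cm kernel "
            f"lattice by more than {OFF_LATTICE_TOL_CM} cm")
    return int(k)


class KernelBank:
    """A collection of P-kernels for one radionuclide, indexed by the
    dummy's lattice offset (dR, dZ) in the active frame.

    Only the dR >= 0, dZ >= 0 quadrant needs to be stored: azimuthal
    symmetry about the seed axis handles the transverse direction and
    mirror symmetry in Z handles the axial sign (pole-symmetric seeds).
    """

    def __init__(self, radionuclide: str, kernels=(),
                 dummy_model: SeedModel | None = None):
        self.radionuclide = radionuclide
        self.dummy_model = dummy_model or build_seed(radionuclide)
        self._kernels: dict[tuple[int, int], PKernel] = {}
        for k in kernels:
            self.add(k)

    def add(self, kernel: PKernel) -> None:
        dx, dy, dz = kernel.dummy_offset_cm
        if abs(dx) > 1e-9 or dy < 0 or dz < 0:
            raise ValueError("store kernels in the canonical quadrant: "
                             "x = 0, R >= 0, Z >= 0")
        self._kernels[(_lattice_key(dy), _lattice_key(dz))] = kernel

    def __len__(self) -> int:
        return len(self._kernels)

    def _canonical(self, dummy_rel: np.ndarray):
        """Rotate/mirror a relative dummy position into the stored quadrant.

        Returns (kernel, transform) where ``transform`` maps query points in
        the active frame into the kernel's frame.
        """
        dx, dy, dz = (float(v) for v in dummy_rel)
        s = math.hypot(dx, dy)
        sep = math.hypot(s, dz)
        if sep > KERNEL_COVERAGE_CM + OFF_LATTICE_TOL_CM:
            raise MissingKernelError(
                f"dummy at separation {sep:.2f} cm exceeds the "
                f"{KERNEL_COVERAGE_CM:.0f} cm kernel coverage")
        zsign = -1.0 if dz < 0 else 1.0
        if s > 1e-12:
            c, sn = dy / s, dx / s  # rotate (dx, dy) -> (0, s)
        else:
            c, sn = 1.0, 0.0

        def transform(points: np.ndarray) -> np.ndarray:
            p = np.asarray(points, float).reshape(-1, 3)
            x = c * p[:, 0] - sn * p[:, 1]
            y = sn * p[:, 0] + c * p[:, 1]
            z = zsign * p[:, 2]
            return np.stack([x, y, z], axis=1)

        key = (_lattice_key(s), _lattice_key(abs(dz)))
        if key not in self._kernels:
            raise MissingKernelError(
                f"no kernel for dummy lattice offset (R, Z) = "
                f"({key[0] * LATTICE_CM:g}, {key[1] * LATTICE_CM:g}) cm "
                f"[{self.radionuclide}]")
        return self._kernels[key], transform

    def p_values(self, dummy_rel, points: np.ndarray) -> np.ndarray:
        """Vectorized P lookup for one dummy at ``dummy_rel`` (active frame).

        Exactly 1.0 wherever the center-ray shadow test misses the dummy;
        nearest-voxel kernel values elsewhere (clamped to the kernel grid).
        """
        points = np.asarray(points, float).reshape(-1, 3)
        dummy_rel = np.asarray(dummy_rel, float)
        out = np.ones(len(points))
        mask = shadow_mask(np.zeros(3), self.dummy_model, dummy_rel, points)
        if not np.any(mask):
            return out
        kernel, transform = self._canonical(dummy_rel)
        q = transform(points[mask])
        g = kernel.grid
        idx = np.floor((q - g.origin_cm[None, :]) / g.voxel_cm + 0.5).astype(int)
        idx = np.clip(idx, 0, np.array(g.shape) - 1)
        vals = g.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        vals = np.where(np.isfinite(vals), vals, 1.0)  # undefined voxels
        out[mask] = vals
        return out

    # ---- persistence ---------------------------------------------------
    def save(self, directory) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        entries = []
        for (ky, kz), kern in sorted(self._kernels.items()):
            stem = f"kernel_R{ky * LATTICE_CM:g}_Z{kz * LATTICE_CM:g}".replace(".", "p")
            kern.grid.save(d, stem=stem)
            entries.append({"dummy_dr_cm": ky * LATTICE_CM,
                            "dummy_dz_cm": kz * LATTICE_CM, "stem": stem})
        manifest = {"radionuclide": self.radionuclide, "kernels": entries}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return d / "manifest.json"

    @classmethod
    def load(cls, directory) -> "KernelBank":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        bank = cls(manifest["radionuclide"])
        for e in manifest["kernels"]:
            grid = DoseGrid.load(d, stem=e["stem"])
            bank.add(PKernel(manifest["radionuclide"],
                             np.array([0.0, e["dummy_dr_cm"], e["dummy_dz_cm"]]),
                             grid))
        return bank

    @classmethod
    def unity(cls, radionuclide: str, grid: DoseGrid | None = None) -> "KernelBank":
        """A bank whose kernels are all exactly 1 (no perturbation)."""
        from .grid import standard_grid

        bank = cls(radionuclide)
        g = grid if grid is not None else standard_grid()
        n = int(KERNEL_COVERAGE_CM / LATTICE_CM)
        for ky in range(n + 1):
            for kz in range(n + 1):
                if ky == 0 and kz == 0:
                    continue
                gg = g.copy_empty()
                gg.values[:] = 1.0
                gg.units = "P"
                bank.add(PKernel(radionuclide,
                                 np.array([0.0, ky * LATTICE_CM, kz * LATTICE_CM]),
                                 gg))
        return bank


def lookup_p(bank: KernelBank, dummy_rel, point) -> float:
    """P-value for one dummy at ``dummy_rel`` and one calculation point,
    both in the active seed's frame.  Exactly 1.0 when the shadow test
    misses; nearest-voxel kernel value otherwise."""
    return float(bank.p_values(dummy_rel, np.asarray(point, float)[None, :])[0])


def p_model_at(plan: ImplantPlan, active_id: str, point, bank: KernelBank,
               neglect_threshold: float | None = None) -> float:
    """Combined P_MODEL at ``point`` (world frame) with ``active_id`` active.

    ``neglect_threshold`` optionally applies the clinical neglect policy:
    single-dummy factors at or above it (e.g. 0.96, a perturbation under 4%)
    are treated as exactly 1.  Default: off, for exact table reproduction.
    """
    active = plan.seed(active_id)
    point_rel = np.asarray(point, float) - active.position_cm
    factors = []
    for seed in plan.seeds:
        if seed.id == active_id:
            continue
        p = lookup_p(bank, seed.position_cm - active.position_cm, point_rel)
        if neglect_threshold is not None and p >= neglect_threshold:
            p = 1.0
        factors.append(p)
    return combine_pvalues(factors)


def corrected_dose(plan: ImplantPlan, grid: DoseGrid, params: TG43Params,
                   bank: KernelBank,
                   neglect_threshold: float | None = None) -> DoseGrid:
    """ISA-corrected implant dose: voxelwise sum over seeds of
    (single-seed TG-43 dose) x (that seed's P_MODEL field).

    Reduces exactly to plain TG-43 superposition when every kernel is unity.
    """
    from .tg43 import _dose_field

    centers = grid.centers()
    total = np.zeros(len(centers))
    for active in sorted(plan.seeds, key=lambda s: s.id):
        rel = centers - active.position_cm[None, :]
        dose = _dose_field(params, active.Sk_U, rel)
        p_field = np.ones(len(centers))
        for other in plan.seeds:
            if other.id == active.id:
                continue
            p = bank.p_values(other.position_cm - active.position_cm, rel)
            if neglect_threshold is not None:
                p = np.where(p >= neglect_threshold, 1.0, p)
            p_field *= p
        total = total + dose * p_field
    out = grid.copy_empty()
    out.values = total.reshape(grid.shape)
    return out
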