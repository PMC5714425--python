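"""TG-43U1 line-source dose-rate engine.

Implements the 2D formalism

    Ddot(r, theta) = Lambda * S_k * G_L(r,theta)/G_L(r0,theta0) * g_L(r) * F(r,theta)

with the line-source geometry function ``G_L = beta / (L r sin(theta))``,
log-linear interpolation of the radial dose function g_L(r), bilinear
interpolation of the 2D anisotropy function F(r,theta), and voxelwise
superposition over multi-seed implants.  The reference point is
(r0, theta0) = (1 cm, 90 deg).

Angles are measured from the seed tip direction (+z of the seed frame);
packaged anisotropy fixtures are pole-symmetric, so the tip choice does not
affect them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grid import DoseGrid
from .plan import ImplantPlan

__all__ = ["TG43Params", "DosePoint", "effective_length",
           "geometry_function_line", "interp_radial", "interp_anisotropy",
           "dose_rate_single", "superpose", "load_params"]

R0_CM = 1.0
THETA0_DEG = 90.0


class DegenerateGeometryError(ValueError):
    """The evaluation point lies on the active line segment."""


@dataclass(frozen=True)
class DosePoint:
    """A point in the source's polar frame: r (cm), theta (deg from tip)."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")

    @classmethod
    def from_away_along(cls, R: float, Z: float) -> "DosePoint":
        """Build from away (R, perpendicular) and along (Z, axial) distances."""
        r = float(np.hypot(R, Z))
        theta = float(np.degrees(np.arctan2(abs(R), Z)))
        return cls(r, theta)


@dataclass
class TG43Params:
    """Per-source dosimetric parameter set.

    Invariants: g_L(1 cm) = 1 and F(r, 90 deg) = 1 within table precision;
    radii strictly increasing; active length positive.
    """

    radionuclide: str
    dose_rate_constant: float       # Lambda, cGy / (h U)
    active_length_cm: float         # L
    radial_table: pd.DataFrame      # columns r_cm, gL
    anisotropy_table: pd.DataFrame  # columns r_cm, theta_deg, F

    def __post_init__(self) -> None:
        if self.active_length_cm <= 0:
            raise ValueError("active length must be positive")
        r = self.radial_table["r_cm"].to_numpy(float)
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial table radii must be strictly increasing")
        g1 = np.interp(R0_CM, r, self.radial_table["gL"].to_numpy(float))
        if abs(g1 - 1.0) > 5e-3:
            raise ValueError(f"g_L(r0=1 cm) = {g1:.4f}, expected 1 within table precision")
        piv = self.anisotropy_table.pivot_table(index="r_cm", columns="theta_deg",
                                                values="F")
        if THETA0_DEG in piv.columns and np.any(np.abs(piv[THETA0_DEG] - 1) > 5e-3):
            raise ValueError("F(r, 90 deg) must be 1 for all tabulated r")
        self._f_interp = RegularGridInterpolator(
            (piv.index.to_numpy(float), piv.columns.to_numpy(float)),
            piv.to_numpy(float), method="linear", bounds_error=False, fill_value=None)
        self._r_knots = r
        self._log_g = np.log(self.radial_table["gL"].to_numpy(float))
        self._theta_range = (piv.columns.min(), piv.columns.max())


def effective_length(n_sources: int, spacing_cm: float) -> float:
    """Effective line-source length of a discrete pellet source.

    TG-43 convention for a train of ``n_sources`` pellets at uniform
    ``spacing_cm``: L_eff = N * spacing (e.g. three pellets at 1.10 mm pitch
    give a 3.30 mm active length).
    """
    if n_sources < 1 or int(n_sources) != n_sources:
        raise ValueError("n_sources must be a positive integer")
    if spacing_cm <= 0:
        raise ValueError("spacing must be positive")
    return n_sources * spacing_cm


def geometry_function_line(r, theta_deg, L: float):
    """Line-source geometry function G_L(r, theta) in 1/cm^2.

    ``beta / (L r sin theta)`` with beta the angle subtended by the active
    line at the point; on the axis (sin theta -> 0) the limiting form
    ``1 / (r^2 - L^2/4)`` applies.  Points on the active segment itself are
    degenerate.  Vectorized over ``r`` and ``theta_deg``.
    """
    if L <= 0:
        raise ValueError("active length must be positive")
    r = np.asarray(r, dtype=float)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    rho = r * np.sin(th)          # perpendicular distance from axis
    z = r * np.cos(th)            # axial coordinate from source center
    half = L / 2.0

    on_axis = np.abs(rho) < 1e-9
    inside = on_axis & (np.abs(z) <= half + 1e-12)
    if np.any(inside) or np.any(np.asarray(r) == 0):
        raise DegenerateGeometryError(
            "point lies on the active line segment; G_L is undefined")

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(rho, z - half) - np.arctan2(rho, z + half)
        g = beta / (L * rho)
        g_axis = 1.0 / (z**2 - half**2)
        out = np.where(on_axis, g_axis, g)
    return float(out) if out.ndim == 0 else out


def interp_radial(params: TG43Params, r) -> np.ndarray:
    """Radial dose function g_L(r), log-linear in r, exact at table knots.

    Radii outside the table range are clamped to the nearest knot with a
    warning (never silent extrapolation).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("r must be positive")
    lo, hi = params._r_knots[0], params._r_knots[-1]
    if np.any(r_arr < lo) or np.any(r_arr > hi):
        warnings.warn(
            f"g_L(r) queried outside table range [{lo}, {hi}] cm; "
            "clamping to nearest knot", stacklevel=2)
    out = np.exp(np.interp(np.clip(r_arr, lo, hi), params._r_knots, params._log_g))
    return float(out) if out.ndim == 0 else out


def interp_anisotropy(params: TG43Params, r, theta_deg) -> np.ndarray:
    """2D anisotropy function F(r, theta), bilinear, exact at grid knots.

    ``theta`` must lie in [0, 180] deg; ``r`` outside the tabulated range is
    clamped to the nearest tabulated radius.
    """
    r_arr = np.asarray(r, dtype=float)
    th = np.asarray(theta_deg, dtype=float)
    if np.any(th < 0) or np.any(th > 180):
        raise ValueError("theta must lie in [0, 180] degrees")
    r_lo = params.anisotropy_table["r_cm"].min()
    r_hi = params.anisotropy_table["r_cm"].max()
    pts = np.stack(np.broadcast_arrays(np.clip(r_arr, r_lo, r_hi), th), axis=-1)
    out = params._f_interp(pts.reshape(-1, 2))
    if r_arr.ndim == 0 and th.ndim == 0:
        return float(out[0])
    return out.reshape(np.broadcast_shapes(r_arr.shape, th.shape))


def dose_rate_single(params: TG43Params, Sk_U: float, point: DosePoint) -> float:
    """Dose rate (cGy/h) at a polar point from a single source of strength Sk."""
    if Sk_U < 0:
        raise ValueError("air-kerma strength must be non-negative")
    L = params.active_length_cm
    g_ref = geometry_function_line(R0_CM, THETA0_DEG, L)
    g_pt = geometry_function_line(point.r, point.theta, L)
    return (params.dose_rate_constant * Sk_U * (g_pt / g_ref)
            * float(interp_radial(params, point.r))
            * float(interp_anisotropy(params, point.r, point.theta)))


def _dose_field(params: TG43Params, Sk_U: float, rel: np.ndarray) -> np.ndarray:
    """Vectorized Eq.-1 dose rate for relative coordinates ``rel`` (n, 3).

    Points falling on a source's active segment get +inf (the formalism
    diverges there); callers see a warning.
    """
    L = params.active_length_cm
    rho = np.hypot(rel[:, 0], rel[:, 1])
    z = rel[:, 2]
    r = np.hypot(rho, z)
    half = L / 2.0
    on_seg = (rho < 1e-9) & (np.abs(z) <= half)
    if np.any(on_seg):
        warnings.warn(f"{int(on_seg.sum())} voxel center(s) on an active "
                      "segment set to +inf", stacklevel=2)
    safe_rho = np.where(on_seg, 1.0, rho)
    safe_z = np.where(on_seg, 10.0, z)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (np.arctan2(safe_rho, safe_z - half)
                - np.arctan2(safe_rho, safe_z + half))
        g = np.where(safe_rho / np.maximum(r, 1e-300) < 1e-9,
                     1.0 / (safe_z**2 - half**2),
                     beta / (L * safe_rho))
    g_ref = geometry_function_line(R0_CM, THETA0_DEG, L)
    theta = np.degrees(np.arctan2(safe_rho, safe_z))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # range clamping handled per call site
        gl = interp_radial(params, np.maximum(r, 1e-6))
        F = interp_anisotropy(params, np.maximum(r, 1e-6), theta)
    dose = params.dose_rate_constant * Sk_U * (g / g_ref) * gl * F
    return np.where(on_seg, np.inf, dose)


def superpose(params: TG43Params, plan: ImplantPlan, grid: DoseGrid) -> DoseGrid:
    """Uncorrected multi-seed dose rate: voxelwise sum of single-seed fields.

    Each seed is evaluated in its local frame (axis along z, parallel seeds).
    Linear in the strengths and invariant to seed ordering.
    """
    centers = grid.centers()
    total = np.zeros(len(centers))
    # canonical accumulation order makes the sum exactly permutation-invariant
    for seed in sorted(plan.seeds, key=lambda s: s.id):
        rel = centers - seed.position_cm[None, :]
        total = total + _dose_field(params, seed.Sk_U, rel)
    out = grid.copy_empty()
    out.values = total.reshape(grid.shape)
    return out


_FIXTURES = {"I125_6702": "i125_6702.json",
             "Ir192_Flexisource": "ir192_flexisource.json"}


def load_params(source) -> TG43Params:
    """Load a TG-43 parameter set.

    ``source`` is either a packaged radionuclide key (``"I125_6702"``,
    ``"Ir192_Flexisource"``) or a path to a metadata JSON whose ``gL_table``
    and ``F_table`` entries name CSV files beside it.
    """
    if source in _FIXTURES:
        base = resources.files("isakernel.data.tg43")
        meta = json.loads((base / _FIXTURES[source]).read_text())
        with resources.as_file(base / meta["gL_table"]) as p:
            radial = pd.read_csv(p, comment="#")
        with resources.as_file(base / meta["F_table"]) as p:
            aniso = pd.read_csv(p, comment="#")
    else:
        path = Path(source)
        meta = json.loads(path.read_text())
        radial = pd.read_csv(path.parent / meta["gL_table"], comment="#")
        aniso = pd.read_csv(path.parent / meta["F_table"], comment="#")
    return TG43Params(meta["radionuclide"], float(meta["lambda_cGy_per_hU"]),
                      float(meta["active_length_cm"]), radial, aniso)
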