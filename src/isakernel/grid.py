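"""Voxel grids for dose rate, perturbation (P) and ISA values.

The along--away convention follows clinical brachytherapy usage: seeds lie
with their long axis on the world z axis ("along", Z), the perpendicular
in-plane coordinate is "away" (R, world y), and x is the out-of-plane slab
index.  Published comparison points are written ``(x, R, Z)`` in cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DoseGrid", "standard_grid"]


@dataclass
class DoseGrid:
    """A regular 3D voxel grid of dose rate (cGy/h) or dimensionless P/ISA.

    ``origin_cm`` is the *center* of voxel ``[0, 0, 0]``; voxel ``[i, j, k]``
    is centered at ``origin + voxel_cm * (i, j, k)`` and owns the half-open
    cube ``[center - voxel/2, center + voxel/2)`` on each axis.
    """

    voxel_cm: float
    origin_cm: np.ndarray
    values: np.ndarray
    units: str = "cGy/h"

    def __post_init__(self) -> None:
        self.origin_cm = np.asarray(self.origin_cm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.voxel_cm <= 0:
            raise ValueError("voxel_cm must be positive")
        if self.origin_cm.shape != (3,) or self.values.ndim != 3:
            raise ValueError("origin_cm must be a 3-vector and values a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (0=x, 1=y/R, 2=z/Z)."""
        n = self.shape[axis]
        return self.origin_cm[axis] + self.voxel_cm * np.arange(n)

    def centers(self) -> np.ndarray:
        """All voxel centers as an (n_voxels, 3) array in C order."""
        ax = [self.axis_centers(i) for i in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def index_of(self, point) -> tuple[int, int, int]:
        """Index of the voxel owning ``point`` (half-open ownership)."""
        p = np.asarray(point, dtype=float)
        idx = np.floor((p - self.origin_cm) / self.voxel_cm + 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise IndexError(f"point {point} lies outside the grid")
        return tuple(int(i) for i in idx)

    def value_at(self, point) -> float:
        return float(self.values[self.index_of(point)])

    def center_of(self, idx) -> np.ndarray:
        return self.origin_cm + self.voxel_cm * np.asarray(idx, dtype=float)

    def copy_empty(self) -> "DoseGrid":
        return DoseGrid(self.voxel_cm, self.origin_cm.copy(),
                        np.zeros(self.shape), units=self.units)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) outer edges of the grid box."""
        lo = self.origin_cm - self.voxel_cm / 2
        hi = self.origin_cm + self.voxel_cm * (np.array(self.shape) - 0.5)
        return lo, hi

    # ---- persistence: flat float64 binary + JSON sidecar -------------
    def save(self, directory, stem: str = "grid") -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.values.astype("<f8").tofile(d / f"{stem}.f64")
        meta = {"shape": list(self.shape), "voxel_cm": self.voxel_cm,
                "origin_cm": self.origin_cm.tolist(), "units": self.units,
                "dtype": "<f8", "order": "C"}
        (d / f"{stem}.json").write_text(json.dumps(meta, indent=1))
        return d / f"{stem}.json"

    @classmethod
    def load(cls, directory, stem: str = "grid") -> "DoseGrid":
        d = Path(directory)
        meta = json.loads((d / f"{stem}.json").read_text())
        vals = np.fromfile(d / f"{stem}.f64", dtype=meta["dtype"])
        vals = vals.reshape(meta["shape"])
        return cls(meta["voxel_cm"], np.array(meta["origin_cm"]), vals,
                   units=meta.get("units", "cGy/h"))

    def slice_csv(self, path, x_index: int = 0) -> None:
        """Write one along-away (R, Z) slice as CSV with coordinate headers."""
        import pandas as pd

        df = pd.DataFrame(self.values[x_index],
                          index=self.axis_centers(1), columns=self.axis_centers(2))
        df.index.name = "R_cm\\Z_cm"
        df.to_csv(path)


def standard_grid(extent_cm: float = 10.0, voxel_cm: float = 0.25,
                  nx: int = 1, units: str = "cGy/h") -> DoseGrid:
    """The tally mesh used throughout: voxel centers at integer multiples of
    ``voxel_cm`` spanning ``[-extent, +extent]`` in R and Z (81 centers per
    axis at the defaults), with ``nx`` out-of-plane slabs centered on x=0.

    Published calculation points such as (0, 1, 1) or (0, 2.5, 0) are voxel
    centers of this mesh.
    """
    n = int(round(2 * extent_cm / voxel_cm)) + 1
    ox = -voxel_cm * (nx - 1) / 2
    origin = np.array([ox, -extent_cm, -extent_cm])
    return DoseGrid(voxel_cm, origin, np.zeros((nx, n, n)), units=units)
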