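"""Implant plans: parallel-seed positions, strengths and validation.

All seeds in a plan share one radionuclide/seed model and are mutually
parallel with their long axes on world z (non-parallel orientations are out
of scope of the perturbation-kernel model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PlanSeed", "ImplantPlan", "SEED_OUTER_DIAMETER_CM"]

SEED_OUTER_DIAMETER_CM = {"I125_6702": 0.080, "Ir192_Flexisource": 0.085}

#: largest active-to-inactive center separation the kernel bank covers (cm)
KERNEL_COVERAGE_CM = 6.0


@dataclass(frozen=True)
class PlanSeed:
    id: str
    position_cm: np.ndarray  # (x, y, z); y is the away (R) axis
    Sk_U: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position_cm",
                           np.asarray(self.position_cm, dtype=float))
        if self.position_cm.shape != (3,):
            raise ValueError("seed position must be a 3-vector (cm)")
        if self.Sk_U < 0:
            raise ValueError("air-kerma strength must be non-negative")


@dataclass
class ImplantPlan:
    seeds: list[PlanSeed]
    radionuclide: str = "I125_6702"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.seeds]
        if len(set(ids)) != len(ids):
            raise ValueError("seed ids must be unique")
        self.validate_geometry()

    def validate_geometry(self) -> None:
        """Seeds must not overlap (center distance >= outer diameter)."""
        od = SEED_OUTER_DIAMETER_CM.get(self.radionuclide, 0.08)
        pos = self.positions()
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = float(np.linalg.norm(pos[i] - pos[j]))
                if d < od:
                    raise ValueError(
                        f"seeds {self.seeds[i].id!r} and {self.seeds[j].id!r} "
                        f"overlap (separation {d:.4f} cm < outer diameter {od} cm)")

    def validate_kernel_coverage(self) -> None:
        """Pairwise separations must be within the kernel bank's 6 cm reach."""
        pos = self.positions()
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = float(np.linalg.norm(pos[i] - pos[j]))
                if d > KERNEL_COVERAGE_CM:
                    raise ValueError(
                        f"seed pair ({self.seeds[i].id!r}, {self.seeds[j].id!r}) "
                        f"separated by {d:.2f} cm exceeds the "
                        f"{KERNEL_COVERAGE_CM:.0f} cm kernel coverage")

    def positions(self) -> np.ndarray:
        return np.array([s.position_cm for s in self.seeds], dtype=float).reshape(-1, 3)

    def seed(self, seed_id: str) -> PlanSeed:
        for s in self.seeds:
            if s.id == seed_id:
                return s
        raise KeyError(f"no seed with id {seed_id!r} in plan")

    def __len__(self) -> int:
        return len(self.seeds)

    # ---- JSON round trip ------------------------------------------------
    @classmethod
    def from_json(cls, path) -> "ImplantPlan":
        obj = json.loads(Path(path).read_text())
        if isinstance(obj, list):  # bare seed array
            obj = {"radionuclide": "I125_6702", "seeds": obj}
        seeds = [PlanSeed(str(s["id"]),
                          np.array([s["x_cm"], s["y_cm"], s["z_cm"]]),
                          float(s["Sk_U"]))
                 for s in obj["seeds"]]
        return cls(seeds, radionuclide=obj.get("radionuclide", "I125_6702"))

    def to_json(self, path) -> None:
        obj = {"radionuclide": self.radionuclide,
               "seeds": [{"id": s.id, "x_cm": s.position_cm[0],
                          "y_cm": s.position_cm[1], "z_cm": s.position_cm[2],
                          "Sk_U": s.Sk_U} for s in self.seeds]}
        Path(path).write_text(json.dumps(obj, indent=1))
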