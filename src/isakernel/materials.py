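"""Material specifications and photon interaction coefficients.

Coefficient tables (``mu/rho`` and ``mu_en/rho`` in cm^2/g versus energy in
keV) are packaged CSV fixtures derived once from standard NIST-style
compilations (see ``scripts/build_material_fixtures.py`` in the repository).
Interpolation is log-log, the standard choice for smoothly power-law
cross sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["MaterialSpec", "get_material", "MATERIAL_DENSITIES", "VACUUM"]

# densities in g/cm^3; resin/steel/core values as used for the seed models
MATERIAL_DENSITIES = {
    "water": 0.998,      # at 22 C
    "titanium": 4.54,
    "resin": 1.2,        # C12H18NCl anion-exchange resin
    "steel304": 8.0,     # AISI 304 (Fe 67.92, Cr 19, Ni 10, Mn 2, Si 1, C 0.08 wt%)
    "iridium": 22.42,
}

COMPOSITIONS = {
    "resin": {"C": 0.6808, "H": 0.0857, "N": 0.0662, "Cl": 0.1674},
    "steel304": {"Fe": 0.6792, "Cr": 0.19, "Ni": 0.10, "Mn": 0.02,
                 "Si": 0.01, "C": 0.0008},
}


@dataclass(frozen=True)
class MaterialSpec:
    """A material with density and photon coefficient tables.

    ``energies_keV`` must be strictly increasing; coefficients positive.
    """

    name: str
    density: float
    energies_keV: np.ndarray
    mu_rho: np.ndarray
    muen_rho: np.ndarray
    composition: dict | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, float)
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if e.size and (np.any(np.diff(e) <= 0)):
            raise ValueError("energies must be strictly increasing")
        for arr in (self.mu_rho, self.muen_rho):
            if e.size and np.any(np.asarray(arr) <= 0):
                raise ValueError("coefficients must be positive")

    def _interp(self, table: np.ndarray, energy_keV) -> np.ndarray:
        e = np.asarray(energy_keV, dtype=float)
        lo, hi = self.energies_keV[0], self.energies_keV[-1]
        tol = 1e-9 * hi
        if np.any(e < lo - tol) or np.any(e > hi + tol):
            raise ValueError(
                f"energy {energy_keV} keV outside {self.name} table "
                f"range [{lo}, {hi}] keV")
        e = np.clip(e, lo, hi)
        out = np.exp(np.interp(np.log(e), np.log(self.energies_keV),
                               np.log(table)))
        return out if out.ndim else float(out)

    def mass_attenuation(self, energy_keV):
        """mu/rho (cm^2/g) at the given energy/energies."""
        return self._interp(self.mu_rho, energy_keV)

    def mass_energy_absorption(self, energy_keV):
        """mu_en/rho (cm^2/g) at the given energy/energies."""
        return self._interp(self.muen_rho, energy_keV)

    def mu(self, energy_keV):
        """Linear attenuation coefficient mu (1/cm)."""
        return self.density * self.mass_attenuation(energy_keV)


# an effectively zero-attenuation placeholder for evacuated capsule interiors
VACUUM = MaterialSpec("vacuum", 0.0, np.array([1.0, 1e4]),
                      np.array([1e-30, 1e-30]), np.array([1e-30, 1e-30]))

_cache: dict[str, MaterialSpec] = {}


def get_material(name: str) -> MaterialSpec:
    """Load a packaged material by name (cached)."""
    if name == "vacuum":
        return VACUUM
    if name in _cache:
        return _cache[name]
    if name not in MATERIAL_DENSITIES:
        raise KeyError(f"unknown material {name!r}; "
                       f"available: {sorted(MATERIAL_DENSITIES)} + ['vacuum']")
    ref = resources.files("isakernel.data.materials") / f"{name}.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    spec = MaterialSpec(name, MATERIAL_DENSITIES[name],
                        df["energy_keV"].to_numpy(float),
                        df["mu_rho"].to_numpy(float),
                        df["muen_rho"].to_numpy(float),
                        composition=COMPOSITIONS.get(name))
    _cache[name] = spec
    return spec
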