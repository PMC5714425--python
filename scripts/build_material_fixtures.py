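"""Derive the committed photon interaction-coefficient fixtures.

Writes ``src/isakernel/data/materials/*.csv`` (columns
``energy_keV,mu_rho,muen_rho`` in cm^2/g).  Values for H, C, N, O, water,
Ti, Fe and Pb are standard NIST-compilation mass attenuation coefficients;
elements without an anchor table (Cl, Cr, Mn, Ni, Si, Ir) are derived by
scaling the photoelectric part of a nearby anchor element as Z^4.7/A and
adding a Klein-Nishina Compton part (Z/A scaling).  Mass energy-absorption
coefficients for metals are approximate (photoelectric fraction x 0.92 +
Compton fraction x the water muen/mu ratio); only water's muen/rho enters
kerma scoring, the metal columns exist for completeness.

Run once; the committed CSVs are what the package and its tests pin.
"""

from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "isakernel" / "data" / "materials"

E_GRID = np.array(
    [5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0,
     100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 600.0, 800.0, 1000.0]
)

# NIST-style mass attenuation coefficients mu/rho (cm^2/g) on E_GRID.
MU = {
    "H": [0.4097, 0.4019, 0.3914, 0.3854, 0.3764, 0.3695, 0.3570, 0.3458,
          0.3355, 0.3260, 0.3091, 0.2944, 0.2651, 0.2429, 0.2112, 0.1893,
          0.1729, 0.1599, 0.1405, 0.1263],
    "C": [19.07, 11.10, 4.576, 2.373, 0.8071, 0.4420, 0.2562, 0.2076,
          0.1871, 0.1753, 0.1610, 0.1514, 0.1347, 0.1229, 0.1066, 0.09546,
          0.08715, 0.08058, 0.07076, 0.06361],
    "N": [31.20, 18.40, 7.562, 3.879, 1.236, 0.6178, 0.3066, 0.2288,
          0.1980, 0.1817, 0.1639, 0.1529, 0.1353, 0.1233, 0.1068, 0.09557,
          0.08719, 0.08063, 0.07081, 0.06364],
    "O": [47.90, 27.90, 11.63, 5.952, 1.836, 0.8651, 0.3779, 0.2585,
          0.2132, 0.1907, 0.1678, 0.1551, 0.1361, 0.1237, 0.1070, 0.09566,
          0.08729, 0.08070, 0.07087, 0.06372],
    "water": [41.90, 24.50, 10.37, 5.329, 1.673, 0.8096, 0.3756, 0.2683,
              0.2269, 0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186,
              0.1061, 0.09687, 0.08956, 0.07865, 0.07072],
    "Ti": [683.8, 432.3, 202.3, 110.7, 35.87, 15.85, 4.972, 2.214,
           1.213, 0.7661, 0.4052, 0.2721, 0.1649, 0.1314, 0.1043, 0.09081,
           0.08191, 0.07529, 0.06572, 0.05891],
    "Fe": [139.8, 84.84, 305.6, 170.6, 57.08, 25.68, 8.176, 3.629,
           1.958, 1.205, 0.5952, 0.3717, 0.1964, 0.1460, 0.1099, 0.09400,
           0.08414, 0.07704, 0.06699, 0.05995],
    "Pb": [730.4, 467.2, 228.7, 130.6, 111.6, 86.36, 30.32, 14.36,
           8.041, 5.021, 2.419, 5.549, 2.014, 0.9985, 0.4026, 0.2323,
           0.1613, 0.1248, 0.0887, 0.07102],
}

MUEN_WATER = np.array(
    [41.19, 23.96, 9.919, 4.944, 1.374, 0.5503, 0.1557, 0.06947,
     0.04223, 0.03190, 0.02597, 0.02546, 0.02764, 0.02967, 0.03192,
     0.03279, 0.03299, 0.03284, 0.03206, 0.03103]
)

Z_A = {"H": 0.9921, "C": 0.4995, "N": 0.4998, "O": 0.5000, "water": 0.5551,
       "Cl": 0.4795, "Si": 0.4985, "Ti": 0.4593, "Cr": 0.4616, "Mn": 0.4551,
       "Fe": 0.4656, "Ni": 0.4771, "Pb": 0.3958, "Ir": 0.4006}

N_A = 6.02214e23
R_E2 = 7.94078e-26  # classical electron radius squared, cm^2


def kn_sigma(e_kev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    a = np.asarray(e_kev, float) / 510.999
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E2 * (t1 + t2 + t3)


def compton(symbol: str) -> np.ndarray:
    """Klein-Nishina Compton mu/rho (cm^2/g) for an element/material."""
    return kn_sigma(E_GRID) * Z_A[symbol] * N_A


def scaled_element(anchor: str, z_anchor: float, z: float, symbol: str) -> np.ndarray:
    """Photoelectric Z^4.7-scaled element built from an anchor element."""
    pe_anchor = np.maximum(np.array(MU[anchor]) - compton(anchor), 0.0)
    # per-gram scaling: (Z/Z_anchor)^4.7 * (A_anchor/A) == (Z/Z_anchor)^3.7 * (Z/A)/(Z_anchor/A_anchor)
    scale = (z / z_anchor) ** 3.7 * Z_A[symbol] / Z_A[anchor]
    return pe_anchor * scale + compton(symbol)


def iridium() -> np.ndarray:
    """Ir from the Pb anchor; crude K-edge shift from 88.0 to 76.1 keV."""
    pe_pb = np.maximum(np.array(MU["Pb"]) - compton("Pb"), 0.0)
    scale = (77 / 82) ** 3.7 * Z_A["Ir"] / Z_A["Pb"]
    pe = pe_pb * scale
    # Between the Ir and Pb K edges Pb lacks the K contribution Ir has:
    # extrapolate Ir's above-edge branch down as E^-3 from the 100 keV point.
    i80 = int(np.argwhere(E_GRID == 80.0)[0, 0])
    i100 = int(np.argwhere(E_GRID == 100.0)[0, 0])
    pe[i80] = pe[i100] * (100.0 / 80.0) ** 3
    return pe + compton("Ir")


def muen_approx(mu: np.ndarray, symbol: str) -> np.ndarray:
    comp = compton(symbol)
    pe = np.maximum(mu - comp, 0.0)
    water_ratio = MUEN_WATER / np.array(MU["water"])
    return pe * 0.92 + comp * water_ratio


def write(name: str, mu: np.ndarray, muen: np.ndarray, note: str) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lines = [f"# {name}: photon mass attenuation / energy-absorption coefficients",
             f"# {note}",
             "energy_keV,mu_rho,muen_rho"]
    for e, m, men in zip(E_GRID, mu, muen):
        lines.append(f"{e:g},{m:.6g},{men:.6g}")
    (OUT / f"{name}.csv").write_text("\n".join(lines) + "\n")
    print("wrote", OUT / f"{name}.csv")


def main() -> None:
    write("water", np.array(MU["water"]), MUEN_WATER,
          "NIST-compilation values, liquid water.")

    ti = np.array(MU["Ti"])
    write("titanium", ti, muen_approx(ti, "Ti"),
          "NIST-compilation mu/rho; muen/rho approximate (see builder).")

    # AISI 304: Fe 67.92, Cr 19, Ni 10, Mn 2, Si 1, C 0.08 (weight %)
    fe = np.array(MU["Fe"])
    cr = scaled_element("Fe", 26, 24, "Cr")
    ni = scaled_element("Fe", 26, 28, "Ni")
    mn = scaled_element("Fe", 26, 25, "Mn")
    si = scaled_element("Ti", 22, 14, "Si")
    c = np.array(MU["C"])
    steel = 0.6792 * fe + 0.19 * cr + 0.10 * ni + 0.02 * mn + 0.01 * si + 0.0008 * c
    write("steel304", steel, muen_approx(steel, "Fe"),
          "AISI 304 mixture rule; Cr/Ni/Mn/Si Z-scaled from anchors (approximate).")

    # resin C12H18NCl (mass fractions from the formula)
    masses = {"C": 12 * 12.011, "H": 18 * 1.008, "N": 14.007, "Cl": 35.453}
    total = sum(masses.values())
    cl = scaled_element("Ti", 22, 17, "Cl")
    resin = (masses["C"] * np.array(MU["C"]) + masses["H"] * np.array(MU["H"])
             + masses["N"] * np.array(MU["N"]) + masses["Cl"] * cl) / total
    write("resin", resin, muen_approx(resin, "water"),
          "C12H18NCl mixture rule; Cl Z-scaled from Ti anchor (approximate).")

    ir = iridium()
    write("iridium", ir, muen_approx(ir, "Ir"),
          "Z-scaled from Pb anchor with shifted K edge (approximate).")


if __name__ == "__main__":
    main()
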