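# isakernel

Interseed-attenuation (ISA) corrections for TG-43U1 brachytherapy dose
calculation.

## The problem

Low-dose-rate brachytherapy implants place tens of encapsulated radioactive
seeds (e.g. I-125 model 6702, or an Ir-192 Flexisource used as an LDR
stand-in) inside the target volume. Treatment planning systems compute dose
with the AAPM TG-43U1 formalism,

```
Ḋ(r, θ) = Λ · S_k · G_L(r,θ)/G_L(r₀,θ₀) · g_L(r) · F(r,θ),
```

and superpose single-seed dose distributions measured in homogeneous
water. That superposition ignores that each seed's titanium or stainless
steel capsule sits in the path of its neighbors' photons. The resulting
dose deficit — interseed attenuation — reaches 10 % and more in dense
implants, and is largest for low-energy sources where photoelectric
absorption in the capsule dominates.

## The model

For a seed taken as *active*, every other (inactive, "dummy") seed
perturbs its dose at a point by a factor

```
P = D(active, with dummy) / D(active, without dummy)  ≤ 1,
```

and a dummy matters only if it blocks the straight line from the active
source to the point (the *shadow rule*; all other dummies contribute
exactly 1). The package combines precomputed single-dummy P kernels
multiplicatively,

```
P_MODEL = P₁ · P₂ · … · P_N,        ISA = 1 − P_MODEL,
```

and applies the per-seed P_MODEL field on top of TG-43 superposition. The
kernels live on the 0.25 cm along–away lattice out to 6 cm seed
separation; azimuthal and mirror symmetry reduce storage to one quadrant.

The package contains five parts:

- `tg43` — the TG-43U1 line-source engine (geometry function, log-linear
  g_L(r), bilinear F(r,θ), multi-seed superposition);
- `seeds` — parametric solid models of the 6702 and Flexisource seeds with
  analytic ray–component path lengths and narrow-beam transmission;
- `isa` — the shadow test, kernel bank, multiplicative combination and the
  ISA-corrected dose grid;
- `transport` — a desk-scale photon Monte Carlo (photoelectric +
  Klein–Nishina Compton, track-length kerma tally in a 40 cm water sphere)
  that generates P kernels and serves as the independent oracle, plus an
  analytic primary-beam kernel builder;
- `validation` — the published three-configuration comparison tables as
  fixtures, with product recomputation and a discrepancy report.

## Worked example

```python
import numpy as np
import isakernel as ik

# the printed case-2 row at (0, 5, 0): four dummies on the line of sight
p = ik.combine_pvalues([0.866, 0.910, 0.935, 0.946])
print(round(p, 3), round(ik.isa_value(p), 3))   # -> 0.697 0.303

# Monte Carlo P for one active Ir-192 seed with four quadrant dummies
model = ik.build_flexisource()
scene = [ik.SceneSeed("A", model, np.zeros(3))] + [
    ik.SceneSeed(f"d{i}", model, np.array([0.0, sy * 0.5, sz * 0.5]))
    for i, (sy, sz) in enumerate([(1, 1), (-1, 1), (1, -1), (-1, -1)])]
est = ik.estimate_pvalues(scene, "A", ik.load_spectrum("Ir192_Flexisource"),
                          ik.TransportConfig(200_000, rng_seed=11),
                          ik.standard_grid(extent_cm=2.0))
print(round(est.value_at((0, 1, 1)), 3))        # -> 0.868
```

The first number says the four stacked dummies cut the active seed's dose
at 5 cm by 30 %. The second is the full-physics transport estimate of a
single shadowed point, which lands on the published joint-simulation value
(≈ 0.87) already at 2×10⁵ histories.

The `examples/` directory holds one narrative script per capability
(`tg43_dose.py`, `table_validation.py`, `shadow_and_kernels.py`,
`mc_pvalues.py`); each builds its own small input and prints what it
computes. A thin CLI offers the same operations from a shell
(`isakernel compute-dose | compute-isa | generate-kernel | validate-tables`).

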