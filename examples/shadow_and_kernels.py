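"""The shadow rule and analytic perturbation kernels.

An inactive seed perturbs the dose of an active neighbor only where it
blocks the straight line from the active source to the point.  This script
tests the rule directly, builds an analytic primary-beam kernel, and
applies the ISA correction to a two-seed dose grid.
"""

import numpy as np

import isakernel as ik

model = ik.build_flexisource()
spectrum = ik.load_spectrum("Ir192_Flexisource")

dummy_pos = np.array([0.0, 1.0, 0.0])
for pt in [(0, 2.5, 0), (0, 2.5, 1.5), (0, -1, 0)]:
    blocked = ik.shadow_test([0, 0, 0], model, dummy_pos, pt)
    print(f"point {pt}: line of sight {'BLOCKED' if blocked else 'clear'}")

grid = ik.standard_grid(extent_cm=4.0)
kern = ik.analytic_kernel(model, model, dummy_pos, spectrum, grid,
                          medium=ik.get_material("water"))
print("\nanalytic kernel P (primary transmission through the dummy):")
for pt in [(0, 2.0, 0.0), (0, 3.0, 0.0), (0, 2.0, 1.5)]:
    print(f"  P at {pt} = {kern.grid.value_at(pt):.4f}")
print("P < 1 only inside the dummy's geometric shadow; the deficit is the")
print("excess attenuation of steel/iridium over the water they displace.")

bank = ik.KernelBank("Ir192_Flexisource")
bank.add(kern)
params = ik.load_params("Ir192_Flexisource")
plan = ik.ImplantPlan([ik.PlanSeed("A", [0, 0, 0], 1.0),
                       ik.PlanSeed("B", [0, 1.0, 0], 1.0)],
                      "Ir192_Flexisource")
plain = ik.superpose(params, plan, grid)
corr = ik.corrected_dose(plan, grid, params, bank)
pt = (0, 2.0, 0.0)
print(f"\ntwo-seed dose at {pt}: {plain.value_at(pt):.4f} cGy/h uncorrected, "
      f"{corr.value_at(pt):.4f} cGy/h ISA-corrected")
print("The corrected value is lower because seed B shadows seed A's photons")
print("on the way to that point (and A shadows B's by symmetry elsewhere).")
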