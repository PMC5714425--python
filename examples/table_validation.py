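"""Reproduce the published multi-seed validation tables.

Every row of the three reference configurations carries printed
single-dummy perturbation factors P_i; the model's prediction is their
product.  This script recomputes all products and the per-table maximum
deviation from the joint-simulation (FMCWS) reference column.
"""

import isakernel as ik

for fixture in ik.load_all_tables():
    out = ik.recompute_table(fixture)
    md = ik.max_discrepancy(fixture)
    print(f"case #{fixture.case_id} {fixture.radionuclide}: "
          f"{len(out)} rows, max |P_MODEL - P_FMCWS| = {md:.1f} pct points")

report = ik.acceptance_report(ik.load_all_tables())
print(f"\nglobal maximum deviation: {report['global_max_diff_pct']} pct "
      f"(published bound {report['global_bound_pct']} pct) -> "
      f"{'PASS' if report['passed'] else 'FAIL'}")

f = ik.load_table(2, "Ir192_Flexisource")
row = ik.recompute_table(f).iloc[0]
print(f"\nexample row, case #2 Ir-192 at (0, 5, 0): P_MODEL = "
      f"{row['p_model_computed']} vs FMCWS {row['p_fmcws_printed']}")
print("All four dummies sit on the line of sight there, so the product of")
print("their individual factors (0.866 x 0.910 x 0.935 x 0.946 = 0.697)")
print("predicts a 30% interseed-attenuation dose deficit.")
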