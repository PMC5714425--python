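{
 "radionuclide": "Ir192_Flexisource",
 "lambda_cGy_per_hU": 1.109,
 "active_length_cm": 0.35,
 "gL_table": "ir192_flexisource_gL.csv",
 "F_table": "ir192_flexisource_F.csv",
 "note": "Dose-rate constant and active length per published Flexisource dosimetry."
}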