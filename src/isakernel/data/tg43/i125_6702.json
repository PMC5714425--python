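{
 "radionuclide": "I125_6702",
 "lambda_cGy_per_hU": 0.966,
 "active_length_cm": 0.33,
 "gL_table": "i125_6702_gL.csv",
 "F_table": "i125_6702_F.csv",
 "note": "Dose-rate constant and active length per TG-43 consensus for model 6702."
}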