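# Validation fixture transcribed verbatim from the published comparison table
# (case #1, Ir-192). p_model_printed stores the numeric printed product; approx_one=1
# marks entries the source annotates as ~1. note flags suspected transcription issues.
x_cm,R_cm,Z_cm,p1,p2,p3,p4,p_model_printed,p_fmcws_printed,approx_one,note
0,2,0,0.999,1,1,1,0.999,1,1,
0,1,0,1,0.999,0.999,1,0.998,1,1,
0,1,1,0.867,1,1,1,0.867,0.867,0,
0,1,-1,1,1,0.866,1,0.866,0.868,0,
0,0.5,0,1,1,1,1,1,1,0,
0,-0.5,0,1,1,1,1,1,1,0,
0,-1,0,1,1,1,1,1,1,0,
0,-2,0,1,1,1,1,1,0.999,0,
0,0,0.5,1,1,1,1,1,1,0,
0,0,-0.5,1,1,1,1,1,1,0,
0,1,1,1,0.867,1,1,0.867,0.867,0,duplicate-coordinates-as-printed
0,-1,-1,1,1,0.868,1,0.868,0.868,0,
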