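# Validation fixture transcribed verbatim from the published comparison table
# (case #3, I-125). p_model_printed stores the numeric printed product; approx_one=1
# marks entries the source annotates as ~1. note flags suspected transcription issues.
x_cm,R_cm,Z_cm,p1,p2,p3,p4,p5,p6,p7,p_model_printed,p_fmcws_printed,approx_one,note
0,0,1,0.64,0.999,1,1,1,1,1,0.639,0.639,0,
0,1,2,0.995,1,0.999,0.998,0.988,1,1,0.98,0.98,0,
0,1.25,1.75,0.998,1,0.999,0.988,0.872,1,1,0.859,0.854,0,
0,1.25,1.25,0.998,1,0.999,0.874,0.998,1,1,0.87,0.867,0,
0,2,-0.5,1,0.997,1,1,0.999,1,1,0.996,0.999,0,
0,3,0,1,0.859,1,0.999,0.999,0.917,0.999,0.785,0.834,0,
0,4,0,1,0.878,0.998,0.999,1,0.905,1,0.792,0.817,0,
0,4,0.25,1,0.865,0.998,1,1,0.903,0.999,0.779,0.79,0,
0,4,1,1,0.93,0.927,0.998,1,0.999,0.964,0.829,0.829,0,
0,4,1.5,1,0.98,0.866,1,1,1,0.924,0.784,0.808,0,
0,4,2.25,0.998,0.999,0.863,0.998,1,0.999,1,0.858,0.85,0,
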