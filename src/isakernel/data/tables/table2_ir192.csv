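# Validation fixture transcribed verbatim from the published comparison table
# (case #2, Ir-192). p_model_printed stores the numeric printed product; approx_one=1
# marks entries the source annotates as ~1. note flags suspected transcription issues.
x_cm,R_cm,Z_cm,p1,p2,p3,p4,p_model_printed,p_fmcws_printed,approx_one,note
0,5,0,0.866,0.91,0.935,0.946,0.697,0.734,0,
0,4,0.75,0.934,1,1,1,0.934,0.932,0,
0,4,-0.75,0.935,1,1,1,0.935,0.933,0,
0,3,3,0.999,0.999,0.999,1,0.997,1,1,
0,2.5,0,0.888,0.941,1,1,0.836,0.845,0,
0,2.5,1,1,1,0.999,1,0.999,1,1,
0,2.5,-1,1,0.999,1,1,0.999,1,1,
0,1.75,0,0.913,1,1,1,0.913,0.913,0,
0,1.5,0.5,0.998,1,1,1,0.998,0.999,1,
0,1.25,0.5,1,1,1,1,1,1,0,
0,1,0.5,1,1,1,1,1,1,0,
0,0.75,0.5,1,1,1,1,1,1,0,
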