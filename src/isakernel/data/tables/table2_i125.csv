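# Validation fixture transcribed verbatim from the published comparison table
# (case #2, I-125). p_model_printed stores the numeric printed product; approx_one=1
# marks entries the source annotates as ~1. note flags suspected transcription issues.
x_cm,R_cm,Z_cm,p1,p2,p3,p4,p_model_printed,p_fmcws_printed,approx_one,note
0,5,0,0.89,0.898,0.933,0.939,0.7,0.747,0,
0,4,0.75,0.887,0.998,1,1,0.885,0.887,0,
0,4,-0.75,0.886,0.999,0.998,1,0.883,0.886,0,
0,3,3,0.999,1,1,1,0.999,0.998,1,
0,2.5,0,0.855,0.913,1,0.999,0.78,0.789,0,
0,2.5,1,0.996,0.999,1,1,0.995,0.994,0,
0,2.5,-1,0.997,0.998,1,1,0.995,0.996,0,
0,1.75,0,0.876,0.998,1,1,0.874,0.87,0,
0,1.5,0.5,0.991,1,1,1,0.991,0.992,0,
0,1.25,0.5,0.998,1,1,1,0.998,0.996,0,
0,1,0.5,0.998,1,1,1,0.998,0.999,0,
0,0.75,0.5,0.999,1,1,1,0.999,0.999,0,
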