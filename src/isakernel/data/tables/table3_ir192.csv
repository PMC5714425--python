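# Validation fixture transcribed verbatim from the published comparison table
# (case #3, Ir-192). p_model_printed stores the numeric printed product; approx_one=1
# marks entries the source annotates as ~1. note flags suspected transcription issues.
x_cm,R_cm,Z_cm,p1,p2,p3,p4,p5,p6,p7,p_model_printed,p_fmcws_printed,approx_one,note
0,0,1,0.803,1,1,1,1,1,1,0.803,0.803,0,
0,1,2,0.999,1,1,1,0.997,1,0.999,0.995,0.997,0,
0,1.25,1.75,1,1,1,0.999,0.925,1,1,0.924,0.923,0,
0,1.25,1.25,1,1,1,0.918,1,1,1,0.918,0.918,0,
0,2,-0.5,1,0.986,1,1,1,1,1,0.986,0.985,0,
0,3,0,1,0.876,1,1,0.999,0.935,1,0.818,0.827,0,
0,4,0,1,0.863,1,1,0.999,0.923,1,0.796,0.808,0,
0,4,0.25,1,0.863,1,1,1,0.93,1,0.803,0.815,0,
0,4,1,1,0.989,0.981,1,1,1,0.987,0.958,0.96,0,
0,4,1.5,1,0.993,0.862,0.999,1,1,0.952,0.814,0.825,0,
0,4,2.25,1,1,0.856,1,1,0.999,1,0.855,0.854,0,
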