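# Synthetic-representative TG-43 radial dose function gL(r) for I-125 model 6702.
# Smooth, normalized, pole-symmetric values standing in for published consensus
# tables; interpolator and formalism tests assert properties, not these numbers.
r_cm,gL
0.5,1.055
1,1.000
2,0.830
3,0.672
4,0.536
5,0.425
6,0.334
7,0.261
8,0.203
9,0.157
10,0.121
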