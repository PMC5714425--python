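# Synthetic-representative TG-43 radial dose function gL(r) for Ir-192 Flexisource.
# Smooth, normalized, pole-symmetric values standing in for published consensus
# tables; interpolator and formalism tests assert properties, not these numbers.
r_cm,gL
0.25,0.990
0.5,0.996
1,1.000
2,1.004
3,1.005
4,1.003
5,0.998
6,0.990
8,0.963
10,0.922
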