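# steel304: photon mass attenuation / energy-absorption coefficients
# AISI 304 mixture rule; Cr/Ni/Mn/Si Z-scaled from anchors (approximate).
energy_keV,mu_rho,muen_rho
5,137.158,126.197
6,83.2737,76.6224
8,297.155,273.389
10,165.883,152.614
15,55.5026,51.045
20,24.9724,22.933
30,7.95371,7.23274
40,3.53283,3.14293
50,1.90811,1.63992
60,1.17592,0.9648
80,0.582846,0.423284
100,0.365363,0.229632
150,0.194541,0.0873889
200,0.145241,0.0534493
300,0.109714,0.0364344
400,0.0939579,0.0321924
500,0.0841486,0.030436
600,0.07707,0.0294035
800,0.0670352,0.0279171
1000,0.0599981,0.0266996
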