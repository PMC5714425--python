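# titanium: photon mass attenuation / energy-absorption coefficients
# NIST-compilation mu/rho; muen/rho approximate (see builder).
energy_keV,mu_rho,muen_rho
5,683.8,629.107
6,432.3,397.726
8,202.3,186.123
10,110.7,101.845
15,35.87,32.9832
20,15.85,14.5409
30,4.972,4.4907
40,2.214,1.93106
50,1.213,1.00198
60,0.7661,0.58935
80,0.4052,0.261378
100,0.2721,0.145271
150,0.1649,0.0613586
200,0.1314,0.0418001
300,0.1043,0.0323259
400,0.09081,0.0300304
500,0.08191,0.0290121
600,0.07529,0.0283274
800,0.06572,0.0271639
1000,0.05891,0.0260842
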