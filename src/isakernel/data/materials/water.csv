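# water: photon mass attenuation / energy-absorption coefficients
# NIST-compilation values, liquid water.
energy_keV,mu_rho,muen_rho
5,41.9,41.19
6,24.5,23.96
8,10.37,9.919
10,5.329,4.944
15,1.673,1.374
20,0.8096,0.5503
30,0.3756,0.1557
40,0.2683,0.06947
50,0.2269,0.04223
60,0.2059,0.0319
80,0.1837,0.02597
100,0.1707,0.02546
150,0.1505,0.02764
200,0.137,0.02967
300,0.1186,0.03192
400,0.1061,0.03279
500,0.09687,0.03299
600,0.08956,0.03284
800,0.07865,0.03206
1000,0.07072,0.03103
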