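# iridium: photon mass attenuation / energy-absorption coefficients
# Z-scaled from Pb anchor with shifted K edge (approximate).
energy_keV,mu_rho,muen_rho
5,585.767,538.915
6,374.697,344.73
8,183.435,168.766
10,104.765,96.3849
15,89.5275,82.3504
20,69.2861,63.7074
30,24.3446,22.3242
40,11.5448,10.5289
50,6.4765,5.85896
60,4.05386,3.62884
80,8.63213,7.84439
100,4.47463,4.02502
150,1.63732,1.42754
200,0.821098,0.68643
300,0.340567,0.257824
400,0.202155,0.139308
500,0.14384,0.0919104
600,0.113483,0.0686974
800,0.0829033,0.0472281
1000,0.0675351,0.0376122
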