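# resin: photon mass attenuation / energy-absorption coefficients
# C12H18NCl mixture rule; Cl Z-scaled from Ti anchor (approximate).
energy_keV,mu_rho,muen_rho
5,61.1441,56.2663
6,37.9363,34.914
8,17.29,15.9147
10,9.37811,8.62952
15,3.09746,2.82891
20,1.45905,1.29269
30,0.577829,0.430644
40,0.35237,0.196285
50,0.267579,0.108419
60,0.22709,0.0693779
80,0.189586,0.0397766
100,0.171372,0.0306877
150,0.14765,0.0272345
200,0.133562,0.029428
300,0.115257,0.0318001
400,0.103053,0.0327166
500,0.0940194,0.0329202
600,0.0869092,0.0327891
800,0.076301,0.0320169
1000,0.0685781,0.0309793
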