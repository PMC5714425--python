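# Synthetic-representative TG-43 2D anisotropy function F(r,theta) for Ir-192 Flexisource.
# Smooth, normalized, pole-symmetric values standing in for published consensus
# tables; interpolator and formalism tests assert properties, not these numbers.
r_cm,theta_deg,F
0.5,0,0.610
0.5,10,0.623
0.5,20,0.660
0.5,30,0.716
0.5,40,0.783
0.5,50,0.852
0.5,60,0.915
0.5,70,0.963
0.5,80,0.992
0.5,90,1.000
0.5,100,0.992
0.5,110,0.963
0.5,120,0.915
0.5,130,0.852
0.5,140,0.783
0.5,150,0.716
0.5,160,0.660
0.5,170,0.623
0.5,180,0.610
1,0,0.650
1,10,0.662
1,20,0.695
1,30,0.745
1,40,0.805
1,50,0.868
1,60,0.924
1,70,0.967
1,80,0.993
1,90,1.000
1,100,0.993
1,110,0.967
1,120,0.924
1,130,0.868
1,140,0.805
1,150,0.745
1,160,0.695
1,170,0.662
1,180,0.650
3,0,0.700
3,10,0.710
3,20,0.738
3,30,0.781
3,40,0.833
3,50,0.887
3,60,0.935
3,70,0.972
3,80,0.994
3,90,1.000
3,100,0.994
3,110,0.972
3,120,0.935
3,130,0.887
3,140,0.833
3,150,0.781
3,160,0.738
3,170,0.710
3,180,0.700
5,0,0.730
5,10,0.739
5,20,0.765
5,30,0.803
5,40,0.850
5,50,0.898
5,60,0.941
5,70,0.975
5,80,0.994
5,90,1.000
5,100,0.994
5,110,0.975
5,120,0.941
5,130,0.898
5,140,0.850
5,150,0.803
5,160,0.765
5,170,0.739
5,180,0.730
7,0,0.760
7,10,0.768
7,20,0.791
7,30,0.825
7,40,0.866
7,50,0.909
7,60,0.948
7,70,0.977
7,80,0.995
7,90,1.000
7,100,0.995
7,110,0.977
7,120,0.948
7,130,0.909
7,140,0.866
7,150,0.825
7,160,0.791
7,170,0.768
7,180,0.760
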