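# Synthetic-representative TG-43 2D anisotropy function F(r,theta) for I-125 model 6702.
# Smooth, normalized, pole-symmetric values standing in for published consensus
# tables; interpolator and formalism tests assert properties, not these numbers.
r_cm,theta_deg,F
0.5,0,0.400
0.5,10,0.416
0.5,20,0.464
0.5,30,0.537
0.5,40,0.629
0.5,50,0.729
0.5,60,0.828
0.5,70,0.913
0.5,80,0.974
0.5,90,1.000
0.5,100,0.974
0.5,110,0.913
0.5,120,0.828
0.5,130,0.729
0.5,140,0.629
0.5,150,0.537
0.5,160,0.464
0.5,170,0.416
0.5,180,0.400
1,0,0.450
1,10,0.465
1,20,0.508
1,30,0.575
1,40,0.660
1,50,0.752
1,60,0.842
1,70,0.920
1,80,0.976
1,90,1.000
1,100,0.976
1,110,0.920
1,120,0.842
1,130,0.752
1,140,0.660
1,150,0.575
1,160,0.508
1,170,0.465
1,180,0.450
2,0,0.500
2,10,0.514
2,20,0.553
2,30,0.614
2,40,0.691
2,50,0.774
2,60,0.856
2,70,0.928
2,80,0.979
2,90,1.000
2,100,0.979
2,110,0.928
2,120,0.856
2,130,0.774
2,140,0.691
2,150,0.614
2,160,0.553
2,170,0.514
2,180,0.500
3,0,0.550
3,10,0.562
3,20,0.598
3,30,0.653
3,40,0.721
3,50,0.797
3,60,0.871
3,70,0.935
3,80,0.981
3,90,1.000
3,100,0.981
3,110,0.935
3,120,0.871
3,130,0.797
3,140,0.721
3,150,0.653
3,160,0.598
3,170,0.562
3,180,0.550
5,0,0.600
5,10,0.611
5,20,0.642
5,30,0.691
5,40,0.752
5,50,0.819
5,60,0.885
5,70,0.942
5,80,0.983
5,90,1.000
5,100,0.983
5,110,0.942
5,120,0.885
5,130,0.819
5,140,0.752
5,150,0.691
5,160,0.642
5,170,0.611
5,180,0.600
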