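# anisotropy function F(r,theta) fixture, own Monte Carlo study
r_cm,theta_deg,value
1.0,0,0.674
1.0,5,0.706
1.0,10,0.790
1.0,15,0.859
1.0,20,0.895
1.0,30,0.972
1.0,45,0.972
1.0,60,0.990
1.0,90,1.000
1.0,120,0.978
1.0,135,0.953
1.0,150,0.886
1.0,160,0.820
1.0,165,0.764
1.0,170,0.701
1.0,175,0.627
2.0,0,0.590
2.0,5,0.629
2.0,10,0.732
2.0,15,0.801
2.0,20,0.835
2.0,30,0.890
2.0,45,0.935
2.0,60,0.957
2.0,90,1.000
2.0,120,0.988
2.0,135,0.965
2.0,150,0.939
2.0,160,0.841
2.0,165,0.754
2.0,170,0.667
2.0,175,0.610
3.0,0,0.566
3.0,5,0.672
3.0,10,0.755
3.0,15,0.809
3.0,20,0.855
3.0,30,0.928
3.0,45,0.976
3.0,60,1.020
3.0,90,1.000
3.0,120,0.979
3.0,135,0.970
3.0,150,0.925
3.0,160,0.867
3.0,165,0.830
3.0,170,0.707
3.0,175,0.619
5.0,0,0.592
5.0,5,0.704
5.0,10,0.796
5.0,15,0.861
5.0,20,0.890
5.0,30,0.905
5.0,45,0.961
5.0,60,0.988
5.0,90,1.000
5.0,120,0.987
5.0,135,0.953
5.0,150,0.919
5.0,160,0.832
5.0,165,0.800
5.0,170,0.757
5.0,175,0.713
10.0,0,0.800
10.0,5,0.825
10.0,10,0.860
10.0,15,0.892
10.0,20,0.925
10.0,30,0.931
10.0,45,0.962
10.0,60,0.995
10.0,90,1.000
10.0,120,0.972
10.0,135,0.957
10.0,150,0.919
10.0,160,0.881
10.0,165,0.849
10.0,170,0.800
10.0,175,0.740
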