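# material: Pt
# density_g_cm3: 21.45
# Klein-Nishina incoherent + Z-power-law photoelectric anchored at Fe/Pb
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total,mu_en
0.001,5022.72,0.159555,331.738,5354.62,5022.72
0.00108564,4267.54,0.159502,283.786,4551.49,4267.54
0.00117862,3625.89,0.159445,242.766,3868.82,3625.89
0.00127956,3080.71,0.159382,207.674,3288.54,3080.71
0.00138914,2617.48,0.159314,177.656,2795.3,2617.48
0.00150811,2221.99,0.159241,151.976,2374.12,2221.99
0.00163726,1863.24,0.159161,130.008,1993.41,1863.24
0.00177748,1562.37,0.159075,111.216,1673.74,1562.37
0.00192971,1310.04,0.158981,95.1398,1405.34,1310.04
0.00209497,1275.52,0.15888,81.3876,1357.07,1275.52
0.00227439,1389.89,0.15877,69.6232,1459.67,1389.89
0.00246917,1510.31,0.15865,59.5593,1570.03,1510.31
0.00268063,1637.62,0.158521,50.9501,1688.73,1637.62
0.0029102,1772.66,0.158381,43.5854,1816.41,1772.66
0.00315944,1678.55,0.15823,37.2852,1716,1678.55
0.00343002,1470.23,0.158066,31.8958,1502.28,1470.23
0.00372377,1287.74,0.157888,27.2853,1315.18,1287.74
0.00404268,1118.07,0.157696,23.3413,1141.57,1118.07
0.0043889,915.19,0.157488,19.9673,935.315,915.192
0.00476477,749.088,0.157263,17.0811,766.327,749.09
0.00517283,612.283,0.157019,14.6121,627.052,612.285
0.00561584,499.486,0.156756,12.4999,512.143,499.488
0.00609679,409.338,0.156472,10.6931,420.188,409.34
0.00661893,341.95,0.156165,9.14743,351.253,341.952
0.00718578,285.644,0.155833,7.82519,293.625,285.646
0.00780118,238.6,0.155475,6.69408,245.449,238.602
0.00846929,195.423,0.155089,5.72647,201.305,195.426
0.00919461,158.664,0.154673,4.89872,163.717,158.666
0.00998205,128.803,0.154224,4.19062,133.148,128.806
0.0108369,123.706,0.153741,3.58488,127.445,123.709
0.011765,119.211,0.15322,3.06669,122.431,119.214
0.0127726,114.838,0.152661,2.62341,117.614,114.841
0.0138665,110.59,0.152059,2.2442,112.986,110.594
0.015054,106.28,0.151414,1.91981,108.351,106.284
0.0163432,98.2278,0.150721,1.6423,100.021,98.2323
0.0177429,90.7758,0.149978,1.40491,92.3306,90.7806
0.0192624,83.88,0.149182,1.20183,85.231,83.8852
0.0209121,72.0214,0.148331,1.02811,73.1978,72.027
0.022703,58.1268,0.147422,0.879501,59.1538,58.1328
0.0246474,46.905,0.146451,0.752371,47.8038,46.9114
0.0267582,37.842,0.145417,0.643618,38.6311,37.8489
0.0290498,30.523,0.144316,0.550584,31.2179,30.5303
0.0315377,24.593,0.143145,0.470999,25.2071,24.6007
0.0342386,19.798,0.141904,0.402917,20.3428,19.8063
0.0371708,15.9314,0.140588,0.344676,16.4167,15.9402
0.0403542,12.8139,0.139197,0.294854,13.2479,12.8232
0.0438102,10.3017,0.137728,0.252233,10.6916,10.3116
0.0475622,8.2761,0.136181,0.215774,8.62805,8.28664
0.0516355,6.6475,0.134554,0.184584,6.96663,6.65865
0.0560576,5.33943,0.132847,0.157903,5.63018,5.3512
0.0608585,4.2868,0.131061,0.135078,4.55294,4.29921
0.0660705,3.44975,0.129195,0.115553,3.6945,3.46281
0.0717288,2.77133,0.127252,0.0988502,2.99743,2.78505
0.0778718,2.22157,0.125232,0.0845616,2.43137,2.23594
0.0783166,2.18758,0.125089,0.0836514,2.39632,2.202
0.0784734,8.85457,0.125039,0.0833342,9.06294,8.869
0.0845408,7.29055,0.123139,0.0723385,7.48603,7.30558
0.0917811,3.45077,0.120975,0.0618821,3.63363,3.46646
0.0996413,4.63885,0.118744,0.0529372,4.81054,4.6552
0.108175,3.8438,0.116451,0.0452852,4.00553,3.86079
0.117439,3.11115,0.1141,0.0387394,3.26399,3.12877
0.127497,2.51343,0.111697,0.0331397,2.65827,2.53167
0.138416,2.02572,0.109247,0.0283494,2.16332,2.04455
0.15027,1.62796,0.106757,0.0242516,1.75897,1.64737
0.163139,1.31757,0.104234,0.0207461,1.44255,1.33753
0.177111,1.06306,0.101683,0.0177473,1.18249,1.08352
0.192279,0.85434,0.0991112,0.0151819,0.968633,0.875294
0.208746,0.691714,0.0965256,0.0129874,0.801227,0.71312
0.226623,0.564077,0.0939324,0.0111101,0.669119,0.585898
0.246031,0.457881,0.0913378,0.00950418,0.558723,0.48008
0.267102,0.369565,0.0887476,0.00813037,0.466443,0.392103
0.289977,0.29614,0.0861674,0.00695515,0.389262,0.318977
0.314811,0.240673,0.0836021,0.0059498,0.330225,0.263768
0.341771,0.197388,0.0810563,0.00508977,0.283534,0.220699
0.371041,0.160613,0.0785339,0.00435405,0.243501,0.184099
0.402818,0.12982,0.0760387,0.00372468,0.209583,0.153439
0.437316,0.107542,0.0735735,0.00318629,0.184302,0.131252
0.474768,0.0882788,0.0711411,0.00272572,0.162146,0.112037
0.515428,0.0725485,0.0687435,0.00233172,0.143624,0.0963143
0.55957,0.0602736,0.0663827,0.00199468,0.128651,0.0840055
0.607492,0.0498223,0.0640603,0.00170635,0.115589,0.0734795
0.659519,0.0420999,0.0617773,0.0014597,0.105337,0.0656424
0.716001,0.0352668,0.059535,0.00124871,0.0960505,0.0586552
0.77732,0.0292392,0.0573343,0.00106821,0.0876418,0.0524351
0.843891,0.0245944,0.055176,0.000913801,0.0806842,0.0475604
0.916163,0.020813,0.0530608,0.000781713,0.0746555,0.043513
0.994625,0.017467,0.0509894,0.000668718,0.0691251,0.0398663
1.07981,0.0151326,0.0489624,0.000572057,0.0646671,0.0371981
1.17228,0.0131071,0.0469806,0.000489367,0.0605772,0.0348075
1.27268,0.0114795,0.0450446,0.00041863,0.0569428,0.0327852
1.38167,0.0105818,0.043155,0.000358118,0.054095,0.0314655
1.5,0.00977578,0.0413125,0.000306353,0.0513946,0.0302124
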