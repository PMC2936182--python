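# material: Ir
# density_g_cm3: 22.56
# Klein-Nishina incoherent + Z-power-law photoelectric anchored at Fe/Pb
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total,mu_en
0.001,5062.42,0.159859,325.999,5388.58,5062.42
0.00108564,4299.35,0.159806,278.876,4578.38,4299.35
0.00117862,3651.27,0.159748,238.565,3890,3651.27
0.00127956,3100.88,0.159686,204.081,3305.12,3100.88
0.00138914,2633.44,0.159618,174.582,2808.18,2633.44
0.00150811,2234.53,0.159544,149.346,2384.03,2234.53
0.00163726,1872.97,0.159464,127.759,2000.89,1872.97
0.00177748,1569.87,0.159378,109.292,1679.32,1569.87
0.00192971,1315.77,0.159284,93.4937,1409.43,1315.78
0.00209497,1278.01,0.159182,79.9794,1358.15,1278.01
0.00227439,1387.29,0.159072,68.4186,1455.87,1387.29
0.00246917,1501.94,0.158952,58.5288,1560.62,1501.94
0.00268063,1622.68,0.158823,50.0686,1672.91,1622.68
0.0029102,1750.28,0.158683,42.8313,1793.27,1750.29
0.00315944,1654.11,0.158531,36.6401,1690.9,1654.11
0.00343002,1447.27,0.158367,31.3439,1478.77,1447.27
0.00372377,1266.28,0.158189,26.8132,1293.25,1266.28
0.00404268,1098.38,0.157996,22.9374,1121.48,1098.38
0.0043889,898.808,0.157788,19.6219,918.588,898.81
0.00476477,735.461,0.157562,16.7856,752.404,735.462
0.00517283,600.971,0.157318,14.3593,615.487,600.972
0.00561584,490.121,0.157055,12.2837,502.562,490.123
0.00609679,402.088,0.15677,10.5081,412.753,402.09
0.00661893,338.112,0.156462,8.98917,347.257,338.114
0.00718578,284.305,0.15613,7.6898,292.151,284.307
0.00780118,239.052,0.155771,6.57826,245.786,239.054
0.00846929,196.181,0.155384,5.62739,201.964,196.183
0.00919461,159.269,0.154967,4.81396,164.238,159.271
0.00998205,129.286,0.154517,4.11811,133.559,129.289
0.0108369,123.894,0.154033,3.52285,127.571,123.897
0.011765,119.124,0.153512,3.01363,122.291,119.127
0.0127726,114.498,0.152951,2.57802,117.229,114.501
0.0138665,110.018,0.152349,2.20537,112.376,110.022
0.015054,105.499,0.151702,1.88659,107.537,105.503
0.0163432,97.3318,0.151007,1.61389,99.0967,97.3363
0.0177429,89.7871,0.150263,1.3806,91.318,89.792
0.0192624,82.8185,0.149466,1.18104,84.149,82.8237
0.0209121,71.0428,0.148614,1.01032,72.2018,71.0484
0.022703,57.3233,0.147702,0.864284,58.3353,57.3293
0.0246474,46.2452,0.14673,0.739354,47.1313,46.2516
0.0267582,37.3004,0.145694,0.632482,38.0786,37.3073
0.0290498,30.0784,0.14459,0.541058,30.7641,30.0857
0.0315377,24.2284,0.143418,0.462849,24.8347,24.2362
0.0342386,19.4994,0.142174,0.395946,20.0375,19.5077
0.0371708,15.6867,0.140856,0.338713,16.1663,15.6956
0.0403542,12.6134,0.139462,0.289752,13.0426,12.6228
0.0438102,10.1378,0.13799,0.247869,10.5237,10.1478
0.0475622,8.14208,0.13644,0.21204,8.49056,8.15265
0.0516355,6.53793,0.13481,0.18139,6.85413,6.5491
0.0560576,5.24993,0.1331,0.155171,5.53821,5.26173
0.0608585,4.21366,0.13131,0.132741,4.47771,4.22609
0.0660705,3.39017,0.129441,0.113554,3.63316,3.40325
0.0717288,2.72268,0.127494,0.0971399,2.94731,2.73642
0.0760349,2.32733,0.126066,0.0869544,2.54035,2.34154
0.0761871,9.24557,0.126016,0.0866246,9.45821,9.25979
0.0778718,8.72961,0.12547,0.0830986,8.93818,8.74401
0.0845408,7.04208,0.123373,0.0710869,7.23654,7.05714
0.0917811,3.35278,0.121205,0.0608114,3.5348,3.3685
0.0996413,4.47845,0.11897,0.0520213,4.64944,4.49483
0.108175,3.71019,0.116672,0.0445017,3.87136,3.72721
0.117439,3.00287,0.114317,0.0380691,3.15526,3.02053
0.127497,2.42537,0.111909,0.0325663,2.56985,2.44365
0.138416,1.95377,0.109455,0.0278589,2.09108,1.97264
0.15027,1.56879,0.106961,0.023832,1.69959,1.58824
0.163139,1.26983,0.104432,0.0203871,1.39465,1.28982
0.177111,1.02443,0.101876,0.0174402,1.14374,1.04493
0.192279,0.82295,0.0992998,0.0149193,0.937169,0.843944
0.208746,0.666176,0.0967093,0.0127627,0.775648,0.687623
0.226623,0.54337,0.0941112,0.0109179,0.648399,0.565233
0.246031,0.441093,0.0915116,0.00933974,0.541944,0.463334
0.267102,0.355946,0.0889166,0.0079897,0.452852,0.378527
0.289977,0.285073,0.0863314,0.00683481,0.378239,0.307954
0.314811,0.23161,0.0837612,0.00584685,0.321218,0.254749
0.341771,0.189958,0.0812106,0.0050017,0.276171,0.213314
0.371041,0.154549,0.0786835,0.00427872,0.237511,0.17808
0.402818,0.124883,0.0761834,0.00366024,0.204727,0.148547
0.437316,0.103451,0.0737136,0.00313116,0.180296,0.127206
0.474768,0.084917,0.0712765,0.00267856,0.158872,0.108721
0.515428,0.0697814,0.0688744,0.00229138,0.140947,0.0935924
0.55957,0.057974,0.0665091,0.00196017,0.126443,0.0817511
0.607492,0.0479231,0.0641822,0.00167683,0.113782,0.0716254
0.659519,0.0404852,0.0618949,0.00143445,0.103815,0.0640725
0.716001,0.0339127,0.0596484,0.0012271,0.0947882,0.0573456
0.77732,0.0281246,0.0574435,0.00104973,0.0866178,0.0513646
0.843891,0.0236562,0.055281,0.000897991,0.0798353,0.0466659
0.916163,0.0200191,0.0531618,0.000768188,0.0739491,0.0427623
0.994625,0.016811,0.0510864,0.000657148,0.0685546,0.0392529
1.07981,0.0145631,0.0490556,0.000562159,0.0641809,0.0366706
1.17228,0.0126212,0.0470701,0.0004809,0.0601722,0.0343628
1.27268,0.0110706,0.0451304,0.000411387,0.0566124,0.0324169
1.38167,0.0102287,0.0432372,0.000351922,0.0538178,0.0311521
1.5,0.00947512,0.0413911,0.000301053,0.0511673,0.0299506
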