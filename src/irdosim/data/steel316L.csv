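# material: steel316L
# density_g_cm3: 8.06
# AISI 316L mass-fraction mixture of anchored element tables
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total,mu_en
0.001,9019.47,0.18584,75.2935,9094.95,9019.47
0.00108564,7386.32,0.185779,64.41,7450.91,7386.32
0.00117862,6048.85,0.185711,55.0997,6104.14,6048.85
0.00127956,4953.54,0.185639,47.1351,5000.86,4953.54
0.00138914,4056.53,0.18556,40.3219,4097.04,4056.53
0.00150811,3319.43,0.185474,34.4934,3354.11,3319.43
0.00163726,2687.23,0.185381,29.5075,2716.92,2687.23
0.00177748,2175.38,0.185281,25.2422,2200.81,2175.38
0.00183716,1998.24,0.185237,23.7071,2022.14,1998.24
0.00184084,1966.94,0.185234,23.6171,1990.75,1966.94
0.00192971,1742.56,0.185172,21.5935,1764.34,1742.56
0.00209497,1407,0.185053,18.4722,1425.66,1407
0.00227439,1134.06,0.184925,15.8021,1150.04,1134.06
0.00246917,914.539,0.184786,13.518,928.242,914.54
0.00268063,737.934,0.184636,11.564,749.683,737.935
0.0029102,595.809,0.184473,9.89242,605.886,595.81
0.00315944,478.9,0.184296,8.4625,487.547,478.901
0.00343002,383.805,0.184105,7.23926,391.229,383.807
0.00372377,307.586,0.183898,6.19284,313.963,307.588
0.00404268,246.384,0.183674,5.29768,251.865,246.386
0.0043889,196.742,0.183432,4.53192,201.457,196.743
0.00476477,157.079,0.18317,3.87684,161.139,157.08
0.00517283,125.319,0.182887,3.31645,128.818,125.32
0.00561584,99.8793,0.18258,2.83706,102.899,99.8812
0.00598301,90.4571,0.182325,2.51542,93.1554,90.4592
0.00599499,87.9256,0.182317,2.50587,90.6143,87.9277
0.00609679,86.9924,0.182249,2.42697,89.6016,86.9945
0.00653246,118.473,0.181949,2.12868,120.829,118.476
0.00654554,119.327,0.18194,2.12061,121.67,119.329
0.00661893,125.457,0.181891,2.07616,127.715,125.459
0.00710489,171.996,0.181559,1.81467,174.005,171.999
0.00711911,173.535,0.18155,1.80779,175.535,173.538
0.00718578,180.893,0.181505,1.77606,182.851,180.896
0.00780118,260.702,0.181088,1.51933,262.403,260.705
0.00832467,254.305,0.180733,1.34295,255.83,254.308
0.00834133,260.555,0.180722,1.33786,262.075,260.558
0.00846929,257.548,0.180638,1.29972,259.029,257.551
0.00919461,207.711,0.180153,1.11184,209.003,207.714
0.00998205,167.507,0.179631,0.95113,168.638,167.511
0.0108369,134.356,0.179068,0.813646,135.349,134.36
0.011765,107.76,0.178462,0.696036,108.635,107.764
0.0127726,86.4341,0.17781,0.595425,87.2074,86.4384
0.0138665,69.3323,0.177109,0.509358,70.0188,69.3369
0.015054,55.6,0.176357,0.435731,56.2121,55.6049
0.0163432,44.2961,0.17555,0.372747,44.8444,44.3014
0.0177429,35.2872,0.174685,0.318868,35.7808,35.2929
0.0192624,28.1069,0.173758,0.272776,28.5534,28.1129
0.01998,25.3746,0.173317,0.254464,25.8036,25.3809
0.02002,26.0813,0.173293,0.253499,26.5093,26.0876
0.0209121,23.0604,0.172767,0.233347,23.4665,23.0669
0.022703,18.2472,0.171708,0.199617,18.6185,18.2542
0.0246474,14.4308,0.170578,0.170763,14.7721,14.4382
0.0267582,11.4048,0.169373,0.14608,11.7203,11.4128
0.0290498,9.0059,0.16809,0.124964,9.29895,9.0144
0.0315377,7.10392,0.166727,0.106901,7.37755,7.11299
0.0342386,5.59626,0.165281,0.0914486,5.85299,5.60592
0.0371708,4.40144,0.163748,0.0782299,4.64342,4.41172
0.0403542,3.45654,0.162128,0.0669219,3.68559,3.46746
0.0438102,2.71976,0.160417,0.0572485,2.93742,2.73135
0.0475622,2.13347,0.158615,0.0489734,2.34106,2.14575
0.0516355,1.67307,0.15672,0.0418944,1.87169,1.68606
0.0560576,1.31325,0.154732,0.0358387,1.50382,1.32696
0.0608585,1.02839,0.152652,0.0306583,1.2117,1.04285
0.0660705,0.813253,0.150479,0.0262267,0.989958,0.828462
0.0717288,0.638087,0.148215,0.0224357,0.808737,0.654058
0.0778718,0.495573,0.145862,0.0191926,0.660628,0.512313
0.0845408,0.389785,0.143424,0.0164184,0.549627,0.407294
0.0917811,0.300973,0.140904,0.0140452,0.455922,0.319249
0.0996413,0.236752,0.138306,0.012015,0.387072,0.255789
0.108175,0.192923,0.135635,0.0102782,0.338836,0.212711
0.117439,0.155342,0.132897,0.00879253,0.297031,0.175866
0.127497,0.122772,0.130098,0.00752159,0.260391,0.144013
0.138416,0.0945924,0.127244,0.00643436,0.228271,0.116527
0.15027,0.0704509,0.124344,0.00550429,0.2003,0.0930528
0.163139,0.057471,0.121405,0.00470866,0.183585,0.0807094
0.177111,0.0458266,0.118434,0.00402803,0.168288,0.0696675
0.192279,0.0354005,0.115439,0.00344579,0.154285,0.059807
0.208746,0.0281241,0.112427,0.00294771,0.143499,0.0530565
0.226623,0.0233251,0.109407,0.00252162,0.135253,0.0487415
0.246031,0.0189563,0.106385,0.00215713,0.127498,0.0448128
0.267102,0.0149881,0.103368,0.00184532,0.120201,0.0412393
0.289977,0.011392,0.100363,0.00157858,0.113333,0.0379913
0.314811,0.00897448,0.0973746,0.0013504,0.1077,0.0358742
0.341771,0.00735099,0.0944094,0.00115521,0.102916,0.0345028
0.371041,0.00589088,0.0914716,0.000988224,0.0983507,0.0332462
0.402818,0.00461517,0.0885652,0.000845378,0.0940258,0.0321251
0.437316,0.00380609,0.085694,0.000723181,0.0902232,0.0314217
0.474768,0.0030985,0.0828608,0.000618647,0.0865779,0.030771
0.515428,0.00252071,0.0800683,0.000529223,0.0831182,0.0302017
0.55957,0.00208541,0.0773186,0.000452725,0.0798567,0.0297269
0.607492,0.0017228,0.0746135,0.000387284,0.0767236,0.0292773
0.659519,0.00141961,0.0719545,0.000331303,0.0737054,0.0288404
0.716001,0.00118126,0.0693428,0.000283414,0.0708075,0.0284226
0.77732,0.00100301,0.0667795,0.000242447,0.068025,0.0280201
0.843891,0.000839805,0.0642656,0.000207402,0.0653128,0.0275891
0.916163,0.000709766,0.0618019,0.000177423,0.0626891,0.0271493
0.994625,0.000630877,0.0593893,0.000151777,0.060172,0.0267202
1.07981,0.000543161,0.0570285,0.000129838,0.0577015,0.0262437
1.17228,0.000498337,0.0547202,0.00011107,0.0553296,0.0257735
1.27268,0.000504909,0.0524652,9.5015e-05,0.0530652,0.0253205
1.38167,0.00057957,0.0502644,8.12808e-05,0.0509252,0.0249037
1.5,0.000683791,0.0481182,6.95319e-05,0.0488716,0.0244871
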