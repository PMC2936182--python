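# material: dry_air
# density_g_cm3: 0.001205
# reference total and energy-absorption grid; Klein-Nishina channel split
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total,mu_en
0.001,3593.1,0.199207,12.6966,3606,3599
0.0015,1184.92,0.198821,5.87643,1191,1188
0.002,524.3,0.198436,3.40196,527.9,526.2
0.003,160.728,0.197673,1.57455,162.5,161.4
0.004,76.7715,0.196917,0.911534,77.88,76.36
0.005,39.4773,0.196169,0.596546,40.27,39.31
0.006,22.7927,0.195429,0.42189,23.41,22.7
0.008,9.48279,0.193969,0.244239,9.921,9.446
0.01,4.76762,0.192538,0.15984,5.12,4.742
0.015,1.35094,0.189078,0.0739798,1.614,1.334
0.02,0.549293,0.185779,0.0428282,0.7779,0.5389
0.03,0.154359,0.179618,0.0198224,0.3538,0.1537
0.04,0.0630446,0.17398,0.0114755,0.2485,0.06833
0.05,0.0316902,0.1688,0.00751007,0.208,0.04098
0.06,0.0181649,0.164024,0.00531128,0.1875,0.03041
0.08,0.00761927,0.155506,0.00307479,0.1662,0.02407
0.1,0.00395806,0.14813,0.00201227,0.1541,0.02325
0.15,0.00131232,0.133356,0.000931351,0.1356,0.02496
0.2,0.000564382,0.122196,0.000539175,0.1233,0.02672
0.3,0.000196527,0.106254,0.000249549,0.1067,0.02872
0.4,0.000145565,0.0952,0.000144468,0.09549,0.02949
0.5,9.65012e-05,0.086929,9.45461e-05,0.08712,0.02966
0.6,6.83191e-05,0.0804148,6.68651e-05,0.08055,0.02953
0.8,6.78739e-05,0.0706334,3.87093e-05,0.07074,0.02882
1,6.15181e-05,0.0634931,2.5333e-05,0.06358,0.02789
1.25,9.06759e-05,0.0567627,1.6579e-05,0.05687,0.02666
1.5,0.000159138,0.0515791,1.1725e-05,0.05175,0.02547
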