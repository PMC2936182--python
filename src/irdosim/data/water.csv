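# material: water
# density_g_cm3: 0.998
# reference total and energy-absorption grid; Klein-Nishina channel split
energy_MeV,mu_photoelectric,mu_incoherent,mu_coherent,mu_total,mu_en
0.001,4064.27,0.221514,13.5129,4078,4065
0.0015,1369.52,0.221085,6.25427,1376,1372
0.002,613.459,0.220657,3.62071,617.3,615.2
0.003,191.004,0.219809,1.67579,192.9,191.7
0.004,81.5909,0.218968,0.970144,82.78,81.91
0.005,41.727,0.218137,0.634903,42.58,41.88
0.006,23.9737,0.217313,0.449017,24.64,23.46
0.008,9.89437,0.21569,0.259944,10.37,9.915
0.01,4.94478,0.214098,0.170118,5.329,4.944
0.015,1.38401,0.210251,0.0787366,1.673,1.374
0.02,0.557435,0.206583,0.045582,0.8096,0.5503
0.03,0.154771,0.199732,0.021097,0.3756,0.1557
0.04,0.0626243,0.193462,0.0122134,0.2683,0.06947
0.05,0.0312048,0.187702,0.00799295,0.2269,0.04223
0.06,0.0178558,0.182391,0.00565279,0.2059,0.0319
0.08,0.00750779,0.17292,0.0032725,0.1837,0.02597
0.1,0.00384091,0.164717,0.00214166,0.1707,0.02546
0.15,0.00121901,0.14829,0.000991235,0.1505,0.02764
0.2,0.000545984,0.13588,0.000573843,0.137,0.02967
0.3,0.000182017,0.118152,0.000265595,0.1186,0.03192
0.4,8.56498e-05,0.105861,0.000153757,0.1061,0.03279
0.5,0.000105995,0.0966634,0.000100625,0.09687,0.03299
0.6,6.90553e-05,0.0894198,7.11644e-05,0.08956,0.03284
0.8,6.57553e-05,0.078543,4.11983e-05,0.07865,0.03206
1,8.98369e-05,0.0706032,2.69619e-05,0.07072,0.03103
1.25,9.32377e-05,0.0631191,1.7645e-05,0.06323,0.02965
1.5,0.000172479,0.057355,1.24789e-05,0.05754,0.02833
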