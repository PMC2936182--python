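# radial dose function g_L(r) comparison fixture; chamber columns and own
# Monte Carlo column plus published comparators; blank = not reported
r_cm,chamber_taf,chamber_norm1,chamber_norm5,this_mc,taylor_brachydose,ballester_geant,williamson_mc,karaiskos_mc,meigooni_tld
1.0,1.011,1.000,1.029,1.000,1.000,1.000,1.000,1.000,1.000
2.0,0.997,0.985,1.013,1.006,1.004,1.005,1.003,1.010,1.007
3.0,0.989,0.979,1.008,1.024,1.005,1.006,1.002,1.000,1.003
4.0,0.981,0.972,1.002,1.012,1.003,1.006,0.997,,1.021
5.0,0.982,0.972,1.000,1.009,0.998,1.001,0.987,0.990,0.987
6.0,0.972,0.961,0.989,0.973,0.992,0.994,0.973,0.980,0.966
8.0,0.942,0.933,0.961,0.972,0.969,0.971,0.933,0.940,0.933
10.0,0.906,0.901,0.925,0.922,0.938,0.938,0.871,0.880,0.872
12.0,0.856,0.851,0.873,0.896,0.897,,0.795,0.800,
14.0,,,,,0.850,,0.682,,
15.0,0.771,0.771,0.790,0.829,0.826,,,0.610,
18.0,0.700,0.702,0.707,0.732,0.740,,,,
20.0,0.632,0.637,0.645,0.673,0.683,,,,
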