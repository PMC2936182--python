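# bare 192Ir photon emission lines (gamma + K x-ray groups)
# energy_MeV,photons_per_decay
0.061486,0.01200
0.063000,0.02050
0.065122,0.02620
0.066831,0.04460
0.071200,0.00240
0.073400,0.01060
0.075700,0.00530
0.077800,0.01010
0.136343,0.00183
0.201311,0.00471
0.205794,0.03310
0.283267,0.00266
0.295957,0.28710
0.308455,0.29700
0.316506,0.82860
0.374485,0.00726
0.416469,0.00670
0.468069,0.47840
0.484575,0.03189
0.489060,0.00438
0.588581,0.04522
0.604411,0.08216
0.612462,0.05340
0.884537,0.00291
1.061480,0.00053
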