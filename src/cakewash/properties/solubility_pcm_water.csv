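w_wash,csat_g_per_g
0.0,0.136364
0.1,0.190
0.2,0.240
0.3,0.260
0.4,0.245
0.5,0.200
0.6,0.145
0.7,0.095
0.8,0.055
0.9,0.030
1.0,0.017024
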