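w_wash,csat_g_per_g
0.0,0.136364
0.1,0.160
0.2,0.185
0.3,0.200
0.4,0.205
0.5,0.200
0.6,0.185
0.7,0.160
0.8,0.130
0.9,0.090
1.0,0.045
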