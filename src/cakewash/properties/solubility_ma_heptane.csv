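w_wash,csat_g_per_g
0.0,0.075269
0.1,0.030
0.2,0.013
0.3,0.0060
0.4,0.0030
0.5,0.0016
0.6,0.00090
0.7,0.00060
0.8,0.00045
0.9,0.00035
1.0,0.00030
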