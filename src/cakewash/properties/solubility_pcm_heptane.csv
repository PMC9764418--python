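w_wash,csat_g_per_g
0.0,0.136364
0.05,0.0950
0.1,0.0620
0.15,0.0400
0.2,0.0270
0.3,0.0182
0.4,0.0148
0.5,0.0135
0.6,0.0125
0.7,0.0118
0.8,0.0112
0.9,0.0108
1.0,0.0105
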