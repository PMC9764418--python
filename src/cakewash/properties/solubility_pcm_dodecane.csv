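w_wash,csat_g_per_g
0.0,0.136364
0.1,0.050
0.2,0.018
0.3,0.0070
0.4,0.0030
0.5,0.0015
0.6,0.00080
0.7,0.00050
0.8,0.00035
0.9,0.00025
1.0,0.00020
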