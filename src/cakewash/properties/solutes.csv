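name,crystal_density_kg_m3,sphericity
paracetamol,1293,0.4127
mefenamic_acid,1260,0.4680
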