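name,density_kg_m3,viscosity_Pa_s,role
isopropanol,786,0.00204,crystallization
2-butanol,806,0.00300,crystallization
water,997,0.00089,wash
heptane,680,0.00039,wash
acetonitrile,776,0.00034,wash
dodecane,746,0.00136,wash
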