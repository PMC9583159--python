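parcel_id,effective_ears_1e4_hm2,grains_per_ear_total,grains_per_ear_filled,thousand_grain_weight_g,total_output_kg_hm2,yield_per_mu_kg
B,406.5,158.9,141.2,23.6,8359.8,557.32
C,363.8,451.1,279.9,25.4,10488,679.2
D,357.8,439.1,349.8,26.4,11014.5,714.3
E,327.7,446.6,292.3,25.3,9640.5,642.7
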