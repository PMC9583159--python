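parcel_id,model,wet_yield_kg_mu,dry_yield_kg_mu
B,wet_ear,854.97,589.93
B,grain,,585.0
CDE,wet_ear,1011.34,728.17
CDE,grain,,733.95
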