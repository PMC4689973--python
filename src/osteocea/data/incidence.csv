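# provenance: paper
age_lower,age_upper,hip,vertebral,nhnv
75,80.0,0.0053,0.0045,0.0076
80,85.0,0.006,0.0045,0.0203
85,,0.015,0.0133,0.0291
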