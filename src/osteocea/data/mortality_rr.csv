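# provenance: placeholder
site,rr_first_year,rr_subsequent
hip,3.0,1.8
vertebral,2.5,1.5
nhnv,1.4,1.0
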