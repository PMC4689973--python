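# provenance: placeholder
cycle,discontinuation_probability
1,0.3
2,0.226
3,0.1
4,0.08
5,0.06
6,0.05
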