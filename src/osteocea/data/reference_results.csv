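# provenance: paper (published base-case totals; outputs of the original model)
strategy,cost,lys,qalys
generic_alendronate,31456,7.9007,5.9866
denosumab,32334,7.9339,6.0386
zoledronate,35138,7.9132,6.0037
risedronate,35232,7.8941,5.9760
ibandronate,35550,7.8867,5.9663
teriparatide,48828,7.9308,6.0279
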