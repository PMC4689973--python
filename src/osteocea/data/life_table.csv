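# provenance: placeholder
age,annual_death_probability
50,0.004158856440018788
51,0.004502929734196304
52,0.0048811557380380455
53,0.005296909417125906
54,0.005753896107155487
55,0.006256183194808362
56,0.006808234697966764
57,0.0074149489809841596
58,0.00808169985331375
59,0.008814381311451513
60,0.009619456194316367
61,0.010504009030231076
62,0.011475803358727
63,0.012543343811476482
64,0.013715943232477157
65,0.015003795106648399
66,0.01641805154636511
67,0.01797090705489801
68,0.01967568824150745
69,0.021546949601800702
70,0.023600575395008705
71,0.02585388754246798
72,0.02832575933337711
73,0.0310367345484861
74,0.034009151392400905
75,0.03726727035213784
76,0.0408374047637432
77,0.044748052459242516
78,0.04903002637066922
79,0.053716581373051686
80,0.05884353393957831
81,0.06444937034464482
82,0.07057533816889183
83,0.07726551472019583
84,0.08456684467330566
85,0.09252913773953086
86,0.10120501550366856
87,0.11064979471440461
88,0.12092129230619697
89,0.13207953530300165
90,0.14418635657005963
91,0.15730485523522575
92,0.1714986986344027
93,0.18683124103838256
94,0.2033644334479946
95,0.22115749873569135
96,0.24026534778835462
97,0.2607367155891992
98,0.2826120019867945
99,0.3059208109486331
100,0.3306791951650345
101,0.35688663075596905
102,0.3845227702781221
103,0.4135440517893887
104,0.4438802776045636
105,0.4754313181832235
106,0.5080641430645327
107,0.5416104294239159
108,0.5758650456220338
109,0.6105857461097299
110,1.0
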