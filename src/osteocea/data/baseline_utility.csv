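# provenance: placeholder
age,utility
50,0.9750000000000001
51,0.9687500000000001
52,0.9625000000000001
53,0.95625
54,0.9500000000000001
55,0.9437500000000001
56,0.9375000000000001
57,0.9312500000000001
58,0.925
59,0.9187500000000001
60,0.9125000000000001
61,0.9062500000000001
62,0.9000000000000001
63,0.89375
64,0.8875000000000001
65,0.8812500000000001
66,0.8750000000000001
67,0.86875
68,0.8625
69,0.8562500000000001
70,0.8500000000000001
71,0.84375
72,0.8375
73,0.83125
74,0.8250000000000001
75,0.8187500000000001
76,0.8125
77,0.80625
78,0.8
79,0.7937500000000001
80,0.7875000000000001
81,0.78125
82,0.775
83,0.76875
84,0.7625000000000001
85,0.7562500000000001
86,0.75
87,0.74375
88,0.7375
89,0.7312500000000001
90,0.725
91,0.71875
92,0.7125
93,0.70625
94,0.7
95,0.69375
96,0.6875
97,0.68125
98,0.675
99,0.66875
100,0.6625
101,0.65625
102,0.65
103,0.64375
104,0.6375
105,0.63125
106,0.625
107,0.61875
108,0.6125
109,0.60625
110,0.6
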