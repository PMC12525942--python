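percentile,boys,girls
1,12.28,12.27
3,13.09,13.15
5,13.55,13.64
15,14.8,14.99
25,15.6,15.85
50,17.2,17.6
75,18.97,19.54
85,19.99,20.67
95,21.83,22.71
97,22.59,23.56
99,24.1,25.24
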