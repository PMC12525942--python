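percentile,boys,girls
1,14.97,14.42
3,15.9,15.38
5,16.42,15.91
15,17.82,17.38
25,18.72,18.32
50,20.5,20.2
75,22.45,22.28
85,23.58,23.48
95,25.6,25.64
97,26.43,26.53
99,28.06,28.3
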