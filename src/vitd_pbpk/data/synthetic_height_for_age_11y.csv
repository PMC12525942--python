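percentile,boys,girls
1,1.283,1.282
3,1.312,1.312
5,1.327,1.328
15,1.366,1.37
25,1.389,1.394
50,1.432,1.44
75,1.475,1.486
85,1.498,1.51
95,1.537,1.552
97,1.552,1.568
99,1.581,1.598
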