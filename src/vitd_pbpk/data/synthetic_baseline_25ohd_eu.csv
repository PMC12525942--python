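percentile,value
5,31.0
25,44.0
50,55.0
75,66.0
95,81.0
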