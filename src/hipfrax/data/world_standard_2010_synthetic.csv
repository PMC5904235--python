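band_lower,band_upper,weight
50,55,0.246
55,60,0.209
60,65,0.172
65,70,0.125
70,75,0.097
75,80,0.070
80,85,0.042
85,,0.028
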