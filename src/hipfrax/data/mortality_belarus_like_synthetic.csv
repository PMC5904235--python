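band_lower,band_upper,sex,death_rate_per_10k
50,55,female,55
55,60,female,80
60,65,female,120
65,70,female,190
70,75,female,320
75,80,female,560
80,85,female,1000
85,,female,2000
50,55,male,150
55,60,male,220
60,65,male,320
65,70,male,450
70,75,male,650
75,80,male,950
80,85,male,1450
85,,male,2400
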