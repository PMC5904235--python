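band_lower,band_upper,sex,count
50,55,female,370000
55,60,female,360000
60,65,female,310000
65,70,female,230000
70,75,female,160000
75,80,female,190000
80,85,female,120000
85,,female,80000
50,55,male,330000
55,60,male,300000
60,65,male,240000
65,70,male,160000
70,75,male,95000
75,80,male,90000
80,85,male,45000
85,,male,25000
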