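band_lower,band_upper,sex,mof_to_hip_ratio
50,55,female,7.5
55,60,female,6.5
60,65,female,5.5
65,70,female,4.5
70,75,female,3.6
75,80,female,3.0
80,85,female,2.6
85,,female,2.4
50,55,male,4.5
55,60,male,4.0
60,65,male,3.5
65,70,male,3.0
70,75,male,2.6
75,80,male,2.3
80,85,male,2.0
85,,male,1.9
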