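bin_low,bin_high,male_count,female_count
3.5,4.5,2,0
4.5,5.5,4,1
5.5,6.5,4,5
6.5,7.5,5,10
7.5,8.5,1,5
8.5,9.5,5,8
9.5,10.5,1,3
10.5,11.5,2,2
11.5,,0,1
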