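statistic,local_2_2,global_2_2,global_3_2,median_dd
Average,91.0,97.1,99.3,0.7
SD,5.5,3.6,1.5,1.2
Min,75.5,84.1,93.2,-1.6
Max,98.3,99.8,100.0,3.1
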