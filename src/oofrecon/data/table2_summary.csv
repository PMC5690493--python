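statistic,local_2_2,global_2_2,global_3_2,median_dd
Average,88.1,96.3,98.7,1.0
SD,5.3,2.6,1.2,1.2
Min,73.4,90.4,95.3,-1.1
Max,98.0,100.0,100.0,2.9
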