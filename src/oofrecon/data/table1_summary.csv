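statistic,local_2_2,global_2_2,median_dd
Average,96.7,98.7,0.0
SD,3.7,1.8,0.6
Min,84.4,92.7,-0.9
Max,100.0,100.0,1.3
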