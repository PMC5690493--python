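mu_per_min,ratio
5,0.978
20,0.984
50,0.989
100,0.993
200,0.996
300,0.998
400,1.000
600,1.001
1000,1.002
2400,1.003
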