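mu,entrance_default,entrance_modified,exit_default,exit_modified
1,0.955,0.978,0.900,0.950
2,0.972,0.986,0.930,0.965
5,0.985,0.993,0.960,0.980
10,0.992,0.996,0.975,0.988
20,0.996,0.998,0.990,0.995
50,0.999,0.9995,0.997,0.9985
100,1.000,1.000,1.000,1.000
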