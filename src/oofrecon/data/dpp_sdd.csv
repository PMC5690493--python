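sdd_mm,ratio_6x,ratio_10xfff
746,1.012,1.001
800,1.006,1.0005
896,1.000,1.000
1000,0.9965,0.998
1100,0.9935,0.996
1196,0.992,0.995
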