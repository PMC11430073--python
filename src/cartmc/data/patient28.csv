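day,total_cart
0,9.230e7
2,1.128e7
3,4.029e7
4,3.106e8
6,1.070e9
11,4.786e8
12,3.259e8
15,2.245e8
19,1.372e8
20,1.340e8
26,7.801e7
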