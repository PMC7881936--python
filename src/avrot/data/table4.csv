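AVR,ratio
2,8.8848
4,8.0729
6,7.3639
8,6.7457
10,6.1983
12,5.7112
14,5.2751
16,4.8817
18,4.5261
20,4.2023
22,3.9068
24,3.6362
26,3.3881
28,3.1603
30,2.9495
32,2.7553
34,2.5753
36,2.4087
38,2.2544
40,2.1112
42,1.9784
44,1.8552
46,1.7409
48,1.6348
50,1.5365
52,1.4452
54,1.3607
56,1.2825
58,1.2102
60,1.1434
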