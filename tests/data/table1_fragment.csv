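AVR,20,21,22,23,24,70
2,2.3,2.4,2.5,2.6,2.7,7.8
4,2.6,2.7,2.8,2.9,3,9
6,2.9,3,3.1,3.2,3.4,9.8
8,3.2,3.3,3.4,3.6,3.7,10.5
10,3.5,3.6,3.8,3.9,4.1,11.7
12,3.7,3.8,4,4.2,4.3,12.8
14,3.9,4,4.2,4.4,4.6,13.9
16,4.1,4.2,4.5,4.7,4.9,15
18,4.3,4.5,4.7,4.9,5.2,16
20,4.5,4.7,5,5.2,5.5,17.3
22,4.9,5.1,5.4,5.7,5.9,18.8
24,5.3,5.5,5.8,6.1,6.4,20.1
26,5.7,6,6.3,6.6,6.9,21.7
28,6,6.4,6.7,7,7.4,23.1
60,17.5,18.3,19.2,20,20.9,61.5
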