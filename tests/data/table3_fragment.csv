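AVR,20,21,22,23,24,70
2,8.15408,8.27012,8.36228,8.42931,8.46827,8.79462
4,7.57368,7.68005,7.73791,7.78601,7.80927,7.89888
6,7.04025,7.13739,7.16903,7.20268,7.21409,7.16873
8,6.54855,6.637,6.64894,6.67153,6.67412,6.537
10,6.09427,6.17446,6.17198,6.18614,6.18232,5.98232
12,5.67363,5.74601,5.73329,5.74124,5.73293,5.49782
14,5.2834,5.34847,5.32888,5.33234,5.32102,5.06923
16,4.92084,4.97903,4.95525,4.95558,4.94246,4.69047
18,4.58353,4.6353,4.60946,4.60776,4.59374,4.34998
20,4.26939,4.31517,4.28895,4.28608,4.27189,4.04111
22,3.97661,4.01684,3.99152,3.98813,3.97433,3.76408
24,3.70362,3.73872,3.71525,3.71187,3.69886,3.51061
26,3.44904,3.47945,3.45849,3.4555,3.44357,3.2801
28,3.21167,3.23781,3.2198,3.21747,3.20683,3.06784
60,1.1265,1.13327,1.13167,1.13336,1.13382,1.11129
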