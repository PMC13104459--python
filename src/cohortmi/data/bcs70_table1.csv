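sweep,age,total,dead,emigrated,respondents,nonrespondents
1,0,18037,0,0,16589,1448
2,5,18037,569,0,13135,4333
3,10,18037,590,0,14867,2580
4,16,18037,623,0,11615,5799
5,26,18037,716,34,9003,8284
6,30,18037,767,235,11261,5774
7,34,18037,820,432,9665,7120
8,38,18037,882,456,8874,7825
9,42,18037,966,433,9841,6797
10,46,18037,986,466,8581,8004
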