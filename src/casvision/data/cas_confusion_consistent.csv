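reference_cas,pred_0,pred_1,pred_2,pred_3,pred_4,pred_5,pred_6,pred_7
0,231,183,79,0,0,0,0,0
1,234,509,325,76,4,0,0,0
2,28,88,507,126,114,10,0,0
3,0,5,43,114,118,3,0,0
4,0,0,10,16,42,17,0,0
5,0,0,0,0,0,68,22,0
6,0,0,0,0,0,0,27,0
7,0,0,0,0,0,0,0,0
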