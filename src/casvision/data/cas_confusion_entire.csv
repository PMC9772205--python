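reference_cas,pred_0,pred_1,pred_2,pred_3,pred_4,pred_5,pred_6,pred_7
0,214,156,101,16,4,3,0,0
1,253,733,589,144,41,2,0,0
2,74,349,713,324,86,20,1,0
3,21,84,219,308,227,54,1,0
4,7,49,63,178,161,86,19,2
5,0,1,12,29,42,44,25,11
6,0,0,0,0,2,1,17,0
7,0,0,0,0,0,1,3,7
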