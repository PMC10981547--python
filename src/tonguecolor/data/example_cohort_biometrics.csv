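patient_id,age,sex,bmi,smoking,cvd_drug,sbp,dbp,tg,hdl_c,ldl_c,hba1c,fpg
1,84,F,27.8,no,yes,120,40,179,60,123,6.3,152
2,77,F,29.3,no,no,138,68,117,71,129,7.0,103
3,71,M,22.2,yes,no,129,73,49,49,134,6.1,132
4,83,M,21.4,yes,yes,176,86,68,60,88,7.2,168
5,77,F,26.2,no,yes,122,80,201,64,132,6.2,128
6,40,F,29.9,yes,no,129,80,154,48,183,6.8,121
7,73,M,24.2,yes,no,133,76,185,43,111,7.7,140
8,85,M,21.4,no,no,160,80,74,80,128,5.6,98
9,82,M,24.3,yes,no,136,89,66,60,114,5.4,102
10,75,F,25.5,no,yes,120,65,117,40,141,6.3,132
11,57,F,21.3,no,yes,99,63,43,69,120,4.9,92
12,76,M,19.5,yes,no,128,72,115,64,134,7.1,160
13,80,F,25.4,no,yes,145,80,190,46,111,5.7,91
14,65,F,25.4,no,yes,137,82,58,63,112,6.4,115
15,64,F,26.1,no,no,148,80,96,54,182,5.8,100
16,56,F,21.4,no,no,126,78,276,53,229,5.7,99
17,69,M,22.3,yes,no,114,68,97,101,100,5.5,96
18,44,F,16.5,yes,no,88,51,144,53,113,5.5,88
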