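patient_id,L_sit,a_sit,b_sit,L_sup,a_sup,b_sup
1,52.5,28.6,4.2,54.0,29.6,6.6
2,41.6,29.4,3.2,40.4,30.2,2.4
3,40.5,25.5,0.7,41.1,29.3,4.0
4,36.0,23.9,2.4,43.5,25.1,5.3
5,44.5,29.8,4.5,47.7,31.5,7.6
6,46.1,22.2,6.7,45.6,24.3,6.2
7,42.1,20.5,2.7,47.6,23.3,4.7
8,38.6,30.0,5.8,39.3,27.6,4.1
9,35.9,28.2,3.0,35.2,30.9,4.1
10,47.3,26.1,8.3,45.9,29.0,9.6
11,46.4,28.9,10.1,43.8,30.5,9.8
12,43.0,24.2,5.7,38.6,26.5,5.0
13,38.8,32.5,6.9,36.5,34.3,7.2
14,42.1,28.0,8.7,38.2,30.3,8.2
15,50.0,27.3,8.3,43.9,29.4,7.5
16,41.2,29.4,5.0,40.6,31.4,5.8
17,42.1,23.6,3.5,44.5,26.2,4.1
18,44.6,25.3,4.8,44.3,26.1,5.2
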