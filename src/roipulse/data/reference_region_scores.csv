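region_id,median_rbs,rank,pixel_count
0,2.88,4,504
1,1.83,9,389
2,1.81,10,473
3,2.98,3,454
4,1.70,12,865
5,1.32,22,1255
6,1.36,19,17
7,1.24,25,414
8,1.97,7,527
9,1.87,8,597
10,3.33,2,775
11,1.98,6,456
12,1.16,28,46
13,1.14,30,57
14,1.33,21,38
15,1.07,31,48
16,1.43,18,124
17,1.36,19,150
18,1.17,26,140
19,1.17,26,179
20,1.16,28,202
21,1.44,17,268
22,1.45,16,186
23,1.49,14,213
24,1.46,15,990
25,1.30,23,312
26,1.27,24,408
27,3.64,1,794
28,2.68,5,955
29,1.81,10,840
30,1.65,13,1174
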