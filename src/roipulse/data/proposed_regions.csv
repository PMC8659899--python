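region_id,name,thickness_um,source_sites,laterality
0,Upper Medial Forehead,1245.63,0,midline
1,Right Upper Lateral Forehead,1297.3,2,right
2,Left Upper Lateral Forehead,1297.3,2,left
3,Lower Medial Forehead,1221.88,1,midline
4,Right Eye,,4;5;6;7;31,right
5,Left Eye,,4;5;6;7;31,left
6,Right Temporal Lobe,1287.96,25,right
7,Left Temporal Lobe,1287.96,25,left
8,Right Lower Lateral Forehead,1212.2,3,right
9,Left Lower Lateral Forehead,1212.2,3,left
10,Glabella,1386.11,8,midline
11,Upper Nasal Dorsum,1527.6,9,midline
12,Right Mid Nasal Sidewall,1794.71,12,right
13,Left Mid Nasal Sidewall,1794.71,12,left
14,Right Lower Nasal Sidewall,2015.89,13,right
15,Left Lower Nasal Sidewall,2015.89,13,left
16,Lower Nasal Dorsum,1496.12,10,midline
17,Nasal Tip,1496.12,17,midline
18,Philtrum,1496.12,16,midline
19,Right Upper Lip,1496.12,21,right
20,Left Upper Lip,1496.12,21,left
21,Lower Nasal Sidewall,2015.89,13,midline
22,Right Nasolabial Fold,1299.08,22,right
23,Left Nasolabial Fold,1299.08,22,left
24,Chin,1211.14,24,midline
25,Right Marionette Fold,1030.28,23,right
26,Left Marionette Fold,1030.28,23,left
27,Right Malar,1086.2,19,right
28,Left Malar,1086.2,19,left
29,Right Lower Cheek,1335.91,20,right
30,Left Lower Cheek,1335.91,20,left
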