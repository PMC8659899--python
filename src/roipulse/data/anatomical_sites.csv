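site_id,name,epi_um,derm_um,ert,drt,rt
0,Upper Medial Forehead,44.70,1200.93,1.51,1.58,1.56
1,Lower Medial Forehead,45.76,1176.11,1.55,1.55,1.53
2,Upper Lateral Forehead,44.80,1252.50,1.52,1.65,1.62
3,Lower Lateral Forehead,39.86,1172.34,1.35,1.54,1.52
4,Upper Medial Eyelid,40.31,758.85,1.36,1.00,1.00
5,Upper Lateral Eyelid,42.39,1088.58,1.43,1.43,1.42
6,Lower Lateral Eyelid,38.58,1227.10,1.30,1.62,1.58
7,Tear Through,47.00,1178.64,1.59,1.55,1.53
8,Glabella,46.59,1339.52,1.58,1.77,1.73
9,Upper Nasal Dorsum,52.19,1475.42,1.76,1.94,1.91
10,Lower Nasal Dorsum,61.60,1198.61,2.08,1.58,1.58
11,Medial Canthus,42.81,840.36,1.45,1.11,1.11
12,Mid Nasal Sidewall,48.45,1746.27,1.64,2.30,2.25
13,Lower Nasal Sidewall,46.70,1969.20,1.58,2.59,2.52
14,ALA,51.57,1941.03,1.74,2.56,2.49
15,Columella,44.17,1160.76,1.49,1.53,1.51
16,Philtrum,48.07,1196.17,1.63,1.58,1.56
17,Nasal Tip,59.77,1288.00,2.02,1.70,1.69
18,Soft Triangle,51.44,1477.47,1.74,1.95,1.91
19,Malar,45.73,1040.46,1.55,1.37,1.36
20,Lower Cheek,44.66,1291.26,1.51,1.70,1.67
21,Upper Lip,62.62,1433.49,2.12,1.89,1.87
22,Nasolabial Fold,48.91,1250.18,1.65,1.65,1.63
23,Marionette Fold,40.87,989.41,1.38,1.30,1.29
24,Chin,45.37,1165.77,1.53,1.54,1.52
25,Temporal,42.18,1245.77,1.43,1.64,1.61
26,Preauricular,37.53,1251.84,1.27,1.65,1.61
27,Upper Helix,42.29,1074.90,1.43,1.42,1.40
28,Mid Helix,56.89,1052.43,1.92,1.39,1.39
29,Conchal Bowl,32.92,999.14,1.11,1.32,1.29
30,Earlobe,44.65,1191.90,1.51,1.57,1.55
31,Lower Medial Eyelid,48.01,868.39,1.62,1.14,1.15
32,Anterior Neck,40.69,1237.68,1.38,1.63,1.60
33,Lateral Neck,32.89,1440.71,1.11,1.90,1.84
34,Posterior Scalp,35.36,1443.86,1.20,1.90,1.85
35,Posterior Auricular,29.57,1724.21,1.00,2.27,2.19
36,Temporal Scalp,33.25,1349.52,1.12,1.78,1.73
37,Anterior Scalp,37.54,1146.13,1.27,1.51,1.48
38,Vertex,37.42,919.45,1.27,1.21,1.20
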