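id,name,side,length_m,r_prox_m,r_dist_m,h_rel,E_Pa,parent
1,ascending_aorta,,0.040,0.01525,0.01405,0.112,400000,0
2,brachiocephalic,,0.034,0.00650,0.00620,0.137,400000,1
3,common_carotid,R,0.177,0.00400,0.00370,0.167,400000,2
4,internal_carotid,R,0.177,0.00300,0.00275,0.192,800000,3
5,external_carotid,R,0.177,0.00200,0.00200,0.232,800000,3
6,subclavian_i,R,0.034,0.00425,0.00407,0.161,400000,2
7,vertebral,R,0.148,0.00200,0.00200,0.232,800000,6
8,subclavian_ii,R,0.015,0.00407,0.00399,0.163,400000,6
9,thyrocervical_trunk,R,0.100,0.00100,0.00100,0.342,800000,8
10,subclavian_iii,R,0.170,0.00399,0.00317,0.173,400000,8
11,brachial_branch,R,0.150,0.00120,0.00120,0.308,800000,10
12,brachial,R,0.235,0.00317,0.00230,0.198,400000,10
13,radial,R,0.235,0.00175,0.00140,0.266,800000,12
15,ulnar_i,R,0.067,0.00215,0.00215,0.223,800000,12
16,interosseous,R,0.079,0.00100,0.00100,0.342,1600000,15
17,ulnar_ii,R,0.171,0.00203,0.00180,0.238,800000,15
19,aortic_arch_i,,0.020,0.01405,0.01349,0.113,400000,1
20,common_carotid,L,0.208,0.00400,0.00370,0.167,400000,19
21,internal_carotid,L,0.177,0.00300,0.00275,0.192,800000,20
22,external_carotid,L,0.177,0.00200,0.00200,0.232,800000,20
23,aortic_arch_ii,,0.039,0.01349,0.01246,0.114,400000,19
24,subclavian_i,L,0.034,0.00425,0.00407,0.161,400000,23
25,vertebral,L,0.148,0.00200,0.00200,0.232,800000,24
26,subclavian_ii,L,0.015,0.00407,0.00399,0.163,400000,24
27,thyrocervical_trunk,L,0.100,0.00100,0.00100,0.342,800000,26
28,subclavian_iii,L,0.170,0.00399,0.00317,0.173,400000,26
29,brachial_branch,L,0.150,0.00120,0.00120,0.308,800000,28
30,brachial,L,0.235,0.00317,0.00230,0.198,400000,28
31,radial,L,0.235,0.00175,0.00140,0.266,800000,30
33,ulnar_i,L,0.067,0.00215,0.00215,0.223,800000,30
34,interosseous,L,0.079,0.00100,0.00100,0.342,1600000,33
35,ulnar_ii,L,0.171,0.00203,0.00180,0.238,800000,33
37,thoracic_i,,0.080,0.01246,0.01058,0.117,400000,23
38,intercostal,,0.073,0.00300,0.00300,0.187,400000,37
39,thoracic_ii,,0.060,0.01058,0.00936,0.120,400000,37
40,costal,,0.073,0.00233,0.00233,0.214,400000,39
41,thoracic_iii,,0.060,0.00936,0.00828,0.124,400000,39
42,celiac_i,,0.020,0.00350,0.00300,0.181,400000,41
43,common_hepatic,,0.066,0.00275,0.00250,0.201,400000,42
44,celiac_ii,,0.020,0.00300,0.00250,0.196,400000,42
45,gastric,,0.071,0.00175,0.00150,0.261,400000,44
46,splenic,,0.063,0.00200,0.00200,0.232,400000,44
47,abdominal_aorta_i,,0.045,0.00828,0.00755,0.128,400000,41
48,superior_mesenteric,,0.059,0.00400,0.00350,0.169,400000,47
49,abdominal_aorta_ii,,0.015,0.00755,0.00732,0.130,400000,47
50,renal,R,0.032,0.00275,0.00275,0.196,400000,49
51,abdominal_aorta_iii,,0.015,0.00732,0.00710,0.131,400000,49
52,renal,L,0.032,0.00275,0.00275,0.196,400000,51
53,abdominal_aorta_iv,,0.065,0.00710,0.00622,0.135,400000,51
54,inferior_mesenteric,,0.050,0.00200,0.00175,0.241,400000,53
55,abdominal_aorta_v,,0.060,0.00622,0.00550,0.141,400000,53
56,common_iliac,R,0.058,0.00400,0.00370,0.167,800000,55
71,common_iliac,L,0.058,0.00400,0.00370,0.167,800000,55
57,internal_iliac,R,0.045,0.00200,0.00200,0.232,800000,56
58,external_iliac,R,0.144,0.00370,0.00314,0.176,800000,56
72,internal_iliac,L,0.045,0.00200,0.00200,0.232,800000,71
73,external_iliac,L,0.144,0.00370,0.00314,0.176,800000,71
59,deep_femoral,R,0.126,0.00255,0.00186,0.221,1600000,58
60,femoral,R,0.254,0.00314,0.00275,0.189,800000,58
74,deep_femoral,L,0.126,0.00255,0.00186,0.221,1600000,73
75,femoral,L,0.254,0.00314,0.00275,0.189,800000,73
61,descending_genicular,R,0.135,0.00197,0.00144,0.255,1600000,60
62,popliteal_i,R,0.137,0.00275,0.00275,0.196,1600000,60
76,descending_genicular,L,0.135,0.00197,0.00144,0.255,1600000,75
77,popliteal_i,L,0.137,0.00275,0.00275,0.196,1600000,75
63,genicular,R,0.050,0.00119,0.00119,0.311,1600000,62
64,popliteal_ii,R,0.052,0.00275,0.00275,0.196,1600000,62
78,genicular,L,0.050,0.00119,0.00119,0.311,1600000,77
79,popliteal_ii,L,0.052,0.00275,0.00275,0.196,1600000,77
65,anterior_tibial,R,0.343,0.00175,0.00175,0.250,1600000,64
67,posterior_tibial_i,R,0.025,0.00250,0.00250,0.206,1600000,64
80,anterior_tibial,L,0.343,0.00175,0.00175,0.250,1600000,79
82,posterior_tibial_i,L,0.025,0.00250,0.00250,0.206,1600000,79
68,peroneal,R,0.318,0.00130,0.00130,0.295,1600000,67
69,posterior_tibial_ii,R,0.322,0.00175,0.00175,0.250,1600000,67
83,peroneal,L,0.318,0.00130,0.00130,0.295,1600000,82
84,posterior_tibial_ii,L,0.322,0.00175,0.00175,0.250,1600000,82
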