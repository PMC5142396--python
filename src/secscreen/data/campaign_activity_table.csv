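row,sp_id,cg_activity_U_per_mL,cg_sd_U_per_mL,cg_relative_pct,cg_relative_sd_pct,bs_activity_U_per_mL,bs_relative_pct
1,Epr,13.1,0.8,100.0,5.8,4.7,100.0
2,YwfM,11.2,1.4,85.5,10.4,0.4,7.7
3,Bpr,11.1,1.0,84.8,7.9,3.0,63.6
4,Vpr,10.5,0.1,80.2,0.6,2.2,47.1
5,YkvV,9.4,1.9,72.0,14.1,1.0,21.8
6,YurI,9.4,0.6,71.9,4.9,1.9,41.5
7,YxiT,9.4,0.3,71.4,2.0,0.9,19.3
8,LipB,9.2,2.1,70.2,15.9,1.6,34.7
9,YurI,8.6,0.6,65.6,4.4,1.9,41.5
10,YckD,8.5,2.3,64.9,17.7,2.8,59.7
11,YfjS,8.0,0.3,60.8,2.2,0.5,10.5
12,Epr,7.8,1.6,59.8,12.1,4.7,100.0
13,YxaK,7.8,1.2,59.5,9.1,0.0,0.0
14,Csn,7.5,2.0,57.4,15.5,3.4,71.7
15,YxaK,8.0,2.3,60.9,17.5,0.0,0.0
16,YndA,7.2,3.5,55.0,27.0,0.5,11.1
17,YxaK,7.1,0.3,54.0,2.4,0.0,0.0
18,YbdN,6.9,1.2,52.4,9.1,2.5,53.7
19,YobB,6.7,0.6,50.9,4.8,2.5,53.3
20,YndA,6.2,3.6,47.2,27.3,0.5,11.1
21,YkvV,6.1,0.6,46.5,4.6,1.0,21.8
22,YurI,5.6,0.9,42.7,6.5,1.9,41.5
23,YwtD,5.9,1.1,45.2,8.6,0.3,5.4
24,YddT,5.7,0.5,43.6,4.0,2.4,51.6
25,YbbE,5.6,0.0,42.7,0.1,2.1,44.8
26,Mdr,5.5,0.1,42.1,0.5,0.4,8.8
27,YobV,5.0,0.2,38.5,1.5,0.0,0.0
28,YvpA,5.0,0.5,38.2,3.9,1.9,40.0
29,YwmC,4.6,0.2,35.2,1.2,1.2,25.1
30,YbbE,4.5,0.5,34.4,4.0,2.1,44.8
31,YwmD,4.5,0.4,34.4,2.8,0.3,5.6
32,YckD,4.4,0.1,33.9,0.7,2.8,59.7
33,YvgO,3.6,0.3,27.5,2.4,0.0,0.0
34,TasA,3.4,3.0,26.1,22.5,0.3,6.2
35,YqxI,3.2,0.2,24.7,1.4,1.4,30.2
36,YndA,3.2,0.6,24.3,4.7,0.5,11.1
37,YogH,2.7,1.7,20.4,12.9,0.0,0.0
38,YfkN,2.1,0.0,16.3,0.2,0.2,4.5
39,LytC,2.1,1.3,16.2,9.6,0.9,19.3
40,WprA,2.1,1.7,15.8,13.0,0.1,2.6
41,YobV,2.0,1.3,15.2,9.8,0.0,0.0
42,YbdN,1.9,1.1,14.9,8.6,2.5,53.7
43,Pel,1.9,0.5,14.5,3.7,2.7,57.2
44,YycP,1.9,2.1,14.2,16.3,0.0,0.0
45,YogH,1.7,0.3,12.9,2.3,0.0,0.0
46,YvpB,1.6,1.7,12.2,13.2,0.0,0.0
47,AmyE,1.5,0.2,11.5,1.8,0.7,14.3
48,YogH,1.3,0.1,10.1,0.5,0.0,0.0
49,TasA,1.2,0.2,9.5,1.5,0.3,6.2
50,AmyE,1.0,0.1,7.8,0.8,0.7,14.3
51,AmyE,0.9,0.2,7.2,1.8,0.7,14.3
52,YbbE,0.9,0.5,6.9,4.1,2.1,44.8
53,YogH,0.9,0.2,6.6,1.4,0.0,0.0
54,YycP,0.8,0.8,6.3,6.1,0.0,0.0
55,DacF,0.8,0.2,5.8,1.2,0.1,3.0
56,RpmG,0.7,0.6,5.4,4.6,0.1,3.0
57,YycP,0.7,0.7,5.4,5.6,0.0,0.0
58,YwgB,0.7,0.2,5.3,1.8,0.0,0.0
59,YwtD,0.5,0.3,3.7,2.4,0.3,5.4
60,YdbK,0.4,0.1,3.0,0.4,0.2,4.7
61,YwtF,0.3,0.0,2.5,0.3,0.0,0.0
62,YwgB,0.3,0.1,2.5,0.9,0.0,0.0
63,YqzC,0.3,0.1,2.0,0.5,0.0,0.0
64,YvpB,0.0,0.0,0.3,0.1,0.0,0.0
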