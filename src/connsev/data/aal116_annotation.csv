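roi_index,name,hemisphere,lobe,network
1,PreCG.L,L,Frontal,DMN
2,PreCG.R,R,Frontal,DMN
3,SFGdor.L,L,prefrontal,EAN
4,SFGdor.R,R,prefrontal,EAN
5,ORBsup.L,L,prefrontal,DMN
6,ORBsup.R,R,prefrontal,DMN
7,MFG.L,L,prefrontal,EAN
8,MFG.R,R,prefrontal,EAN
9,ORBmid.L,L,prefrontal,DMN
10,ORBmid.R,R,prefrontal,DMN
11,IFGoperc.L,L,prefrontal,EAN
12,IFGoperc.R,R,prefrontal,EAN
13,IFGtriang.L,L,prefrontal,EAN
14,IFGtriang.R,R,prefrontal,EAN
15,ORBinf.L,L,prefrontal,DMN
16,ORBinf.R,R,prefrontal,DMN
17,ROL.L,L,Frontal,SMN
18,ROL.R,R,Frontal,SMN
19,SMA.L,L,Frontal,SMN
20,SMA.R,R,Frontal,SMN
21,OLF.L,L,prefrontal,SBN
22,OLF.R,R,prefrontal,SBN
23,SFGmed.L,L,prefrontal,DMN
24,SFGmed.R,R,prefrontal,DMN
25,ORBsupmed.L,L,prefrontal,DMN
26,ORBsupmed.R,R,prefrontal,DMN
27,REC.L,L,prefrontal,DMN
28,REC.R,R,prefrontal,DMN
29,INS.L,L,Insula,SBN
30,INS.R,R,Insula,SBN
31,ACG.L,L,Insula,DMN
32,ACG.R,R,Insula,DMN
33,DCG.L,L,Insula,EAN
34,DCG.R,R,Insula,EAN
35,PCG.L,L,Insula,DMN
36,PCG.R,R,Insula,DMN
37,HIP.L,L,Temporal,SBN
38,HIP.R,R,Temporal,SBN
39,PHG.L,L,Temporal,SBN
40,PHG.R,R,Temporal,SBN
41,AMYG.L,L,Temporal,SBN
42,AMYG.R,R,Temporal,SBN
43,CAL.L,L,Occipital,Visual
44,CAL.R,R,Occipital,Visual
45,CUN.L,L,Occipital,Visual
46,CUN.R,R,Occipital,Visual
47,LING.L,L,Occipital,Visual
48,LING.R,R,Occipital,Visual
49,SOG.L,L,Occipital,Visual
50,SOG.R,R,Occipital,Visual
51,MOG.L,L,Occipital,Visual
52,MOG.R,R,Occipital,Visual
53,IOG.L,L,Occipital,Visual
54,IOG.R,R,Occipital,Visual
55,FFG.L,L,Temporal,Visual
56,FFG.R,R,Temporal,Visual
57,PoCG.L,L,Parietal,SMN
58,PoCG.R,R,Parietal,SMN
59,SPG.L,L,Parietal,EAN
60,SPG.R,R,Parietal,EAN
61,IPL.L,L,Parietal,EAN
62,IPL.R,R,Parietal,EAN
63,SMG.L,L,Parietal,EAN
64,SMG.R,R,Parietal,EAN
65,ANG.L,L,Parietal,EAN
66,ANG.R,R,Parietal,EAN
67,PCUN.L,L,Parietal,DMN
68,PCUN.R,R,Parietal,DMN
69,PCL.L,L,Parietal,SMN
70,PCL.R,R,Parietal,SMN
71,CAU.L,L,Insula,SBN
72,CAU.R,R,Insula,SBN
73,PUT.L,L,Insula,SBN
74,PUT.R,R,Insula,SBN
75,PAL.L,L,Insula,SBN
76,PAL.R,R,Insula,SBN
77,THA.L,L,Insula,SBN
78,THA.R,R,Insula,SBN
79,HES.L,L,Temporal,SMN
80,HES.R,R,Temporal,SMN
81,STG.L,L,Temporal,SMN
82,STG.R,R,Temporal,SMN
83,TPOsup.L,L,Temporal,DMN
84,TPOsup.R,R,Temporal,DMN
85,MTG.L,L,Temporal,DMN
86,MTG.R,R,Temporal,DMN
87,TPOmid.L,L,Temporal,DMN
88,TPOmid.R,R,Temporal,DMN
89,ITG.L,L,Temporal,DMN
90,ITG.R,R,Temporal,DMN
91,CRBLCrus1.L,L,Cerebellum,Cerebel
92,CRBLCrus1.R,R,Cerebellum,Cerebel
93,CRBLCrus2.L,L,Cerebellum,Cerebel
94,CRBLCrus2.R,R,Cerebellum,Cerebel
95,CRBL3.L,L,Cerebellum,Cerebel
96,CRBL3.R,R,Cerebellum,Cerebel
97,CRBL45.L,L,Cerebellum,Cerebel
98,CRBL45.R,R,Cerebellum,Cerebel
99,CRBL6.L,L,Cerebellum,Cerebel
100,CRBL6.R,R,Cerebellum,Cerebel
101,CRBL7b.L,L,Cerebellum,Cerebel
102,CRBL7b.R,R,Cerebellum,Cerebel
103,CRBL8.L,L,Cerebellum,Cerebel
104,CRBL8.R,R,Cerebellum,Cerebel
105,CRBL9.L,L,Cerebellum,Cerebel
106,CRBL9.R,R,Cerebellum,Cerebel
107,CRBL10.L,L,Cerebellum,Cerebel
108,CRBL10.R,R,Cerebellum,Cerebel
109,Vermis12,none,Vermis,Cerebel
110,Vermis3,none,Vermis,Cerebel
111,Vermis45,none,Vermis,Cerebel
112,Vermis6,none,Vermis,Cerebel
113,Vermis7,none,Vermis,Cerebel
114,Vermis8,none,Vermis,Cerebel
115,Vermis9,none,Vermis,Cerebel
116,Vermis10,none,Vermis,Cerebel
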