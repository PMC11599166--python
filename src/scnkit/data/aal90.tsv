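index	name	abbreviation
1	Precentral gyrus L	PreCG.L
2	Precentral gyrus R	PreCG.R
3	Superior frontal gyrus, dorsolateral L	SFGdor.L
4	Superior frontal gyrus, dorsolateral R	SFGdor.R
5	Superior frontal gyrus, orbital part L	ORBsup.L
6	Superior frontal gyrus, orbital part R	ORBsup.R
7	Middle frontal gyrus L	MFG.L
8	Middle frontal gyrus R	MFG.R
9	Middle frontal gyrus, orbital part L	ORBmid.L
10	Middle frontal gyrus, orbital part R	ORBmid.R
11	Inferior frontal gyrus, opercular part L	IFGoperc.L
12	Inferior frontal gyrus, opercular part R	IFGoperc.R
13	Inferior frontal gyrus, triangular part L	IFGtriang.L
14	Inferior frontal gyrus, triangular part R	IFGtriang.R
15	Inferior frontal gyrus, orbital part L	ORBinf.L
16	Inferior frontal gyrus, orbital part R	ORBinf.R
17	Rolandic operculum L	ROL.L
18	Rolandic operculum R	ROL.R
19	Supplementary motor area L	SMA.L
20	Supplementary motor area R	SMA.R
21	Olfactory cortex L	OLF.L
22	Olfactory cortex R	OLF.R
23	Superior frontal gyrus, medial L	SFGmed.L
24	Superior frontal gyrus, medial R	SFGmed.R
25	Superior frontal gyrus, medial orbital L	ORBsupmed.L
26	Superior frontal gyrus, medial orbital R	ORBsupmed.R
27	Gyrus rectus L	REC.L
28	Gyrus rectus R	REC.R
29	Insula L	INS.L
30	Insula R	INS.R
31	Anterior cingulate and paracingulate gyri L	ACG.L
32	Anterior cingulate and paracingulate gyri R	ACG.R
33	Median cingulate and paracingulate gyri L	DCG.L
34	Median cingulate and paracingulate gyri R	DCG.R
35	Posterior cingulate gyrus L	PCG.L
36	Posterior cingulate gyrus R	PCG.R
37	Hippocampus L	HIP.L
38	Hippocampus R	HIP.R
39	Parahippocampal gyrus L	PHG.L
40	Parahippocampal gyrus R	PHG.R
41	Amygdala L	AMYG.L
42	Amygdala R	AMYG.R
43	Calcarine fissure and surrounding cortex L	CAL.L
44	Calcarine fissure and surrounding cortex R	CAL.R
45	Cuneus L	CUN.L
46	Cuneus R	CUN.R
47	Lingual gyrus L	LING.L
48	Lingual gyrus R	LING.R
49	Superior occipital gyrus L	SOG.L
50	Superior occipital gyrus R	SOG.R
51	Middle occipital gyrus L	MOG.L
52	Middle occipital gyrus R	MOG.R
53	Inferior occipital gyrus L	IOG.L
54	Inferior occipital gyrus R	IOG.R
55	Fusiform gyrus L	FFG.L
56	Fusiform gyrus R	FFG.R
57	Postcentral gyrus L	PoCG.L
58	Postcentral gyrus R	PoCG.R
59	Superior parietal gyrus L	SPG.L
60	Superior parietal gyrus R	SPG.R
61	Inferior parietal gyrus L	IPL.L
62	Inferior parietal gyrus R	IPL.R
63	Supramarginal gyrus L	SMG.L
64	Supramarginal gyrus R	SMG.R
65	Angular gyrus L	ANG.L
66	Angular gyrus R	ANG.R
67	Precuneus L	PCUN.L
68	Precuneus R	PCUN.R
69	Paracentral lobule L	PCL.L
70	Paracentral lobule R	PCL.R
71	Caudate nucleus L	CAU.L
72	Caudate nucleus R	CAU.R
73	Putamen L	PUT.L
74	Putamen R	PUT.R
75	Pallidum L	PAL.L
76	Pallidum R	PAL.R
77	Thalamus L	THA.L
78	Thalamus R	THA.R
79	Heschl gyrus L	HES.L
80	Heschl gyrus R	HES.R
81	Superior temporal gyrus L	STG.L
82	Superior temporal gyrus R	STG.R
83	Temporal pole: superior temporal gyrus L	TPOsup.L
84	Temporal pole: superior temporal gyrus R	TPOsup.R
85	Middle temporal gyrus L	MTG.L
86	Middle temporal gyrus R	MTG.R
87	Temporal pole: middle temporal gyrus L	TPOmid.L
88	Temporal pole: middle temporal gyrus R	TPOmid.R
89	Inferior temporal gyrus L	ITG.L
90	Inferior temporal gyrus R	ITG.R
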