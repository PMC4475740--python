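index	label_value	abbreviation	hemisphere	lobe
0	1	PreCG	left	frontal
1	2	PreCG	right	frontal
2	3	SFGdor	left	frontal
3	4	SFGdor	right	frontal
4	5	ORBsup	left	frontal
5	6	ORBsup	right	frontal
6	7	MFG	left	frontal
7	8	MFG	right	frontal
8	9	ORBmid	left	frontal
9	10	ORBmid	right	frontal
10	11	IFGoperc	left	frontal
11	12	IFGoperc	right	frontal
12	13	IFGtriang	left	frontal
13	14	IFGtriang	right	frontal
14	15	ORBinf	left	frontal
15	16	ORBinf	right	frontal
16	17	ROL	left	frontal
17	18	ROL	right	frontal
18	19	SMA	left	frontal
19	20	SMA	right	frontal
20	21	OLF	left	frontal
21	22	OLF	right	frontal
22	23	SFGmed	left	frontal
23	24	SFGmed	right	frontal
24	25	ORBsupmed	left	frontal
25	26	ORBsupmed	right	frontal
26	27	REC	left	frontal
27	28	REC	right	frontal
28	29	INS	left	limbic
29	30	INS	right	limbic
30	31	ACG	left	limbic
31	32	ACG	right	limbic
32	33	MCC	left	limbic
33	34	MCC	right	limbic
34	35	PCC	left	limbic
35	36	PCC	right	limbic
36	37	HIP	left	limbic
37	38	HIP	right	limbic
38	39	PHG	left	limbic
39	40	PHG	right	limbic
40	41	AMYG	left	limbic
41	42	AMYG	right	limbic
42	43	CAL	left	occipital
43	44	CAL	right	occipital
44	45	CUN	left	occipital
45	46	CUN	right	occipital
46	47	LING	left	occipital
47	48	LING	right	occipital
48	49	SOG	left	occipital
49	50	SOG	right	occipital
50	51	MOG	left	occipital
51	52	MOG	right	occipital
52	53	IOG	left	occipital
53	54	IOG	right	occipital
54	55	FFG	left	temporal
55	56	FFG	right	temporal
56	57	PoCG	left	parietal
57	58	PoCG	right	parietal
58	59	SPG	left	parietal
59	60	SPG	right	parietal
60	61	IPL	left	parietal
61	62	IPL	right	parietal
62	63	SMG	left	parietal
63	64	SMG	right	parietal
64	65	ANG	left	parietal
65	66	ANG	right	parietal
66	67	PCUN	left	parietal
67	68	PCUN	right	parietal
68	69	PCL	left	parietal
69	70	PCL	right	parietal
70	71	CAU	left	subcortical
71	72	CAU	right	subcortical
72	73	PUT	left	subcortical
73	74	PUT	right	subcortical
74	75	PAL	left	subcortical
75	76	PAL	right	subcortical
76	77	THA	left	subcortical
77	78	THA	right	subcortical
78	79	HES	left	temporal
79	80	HES	right	temporal
80	81	STG	left	temporal
81	82	STG	right	temporal
82	83	TPOsup	left	temporal
83	84	TPOsup	right	temporal
84	85	MTG	left	temporal
85	86	MTG	right	temporal
86	87	TPOmid	left	temporal
87	88	TPOmid	right	temporal
88	89	ITG	left	temporal
89	90	ITG	right	temporal
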