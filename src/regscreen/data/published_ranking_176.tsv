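rank	identity	delay_min	fitness
1	ZNF331	100	62.14
2	C16orf72	40	61.91
3	ANKRD49	40	61.40
4	ZNF331	100	60.49
5	EXOC3L2	0	59.49
6	SKI	40	58.27
7	PDE4D	80	58.19
8	RNF6	40	58.09
9	BBX	40	58.06
10	RNF144A	40	57.28
11	PRKAR2A	40	57.25
12	MEF2D	100	57.17
13	IRS2	100	57.12
14	CCDC109B	40	56.79
15	MTMR12	40	56.73
16	EHBP1	40	55.84
17	AGGF1	40	55.19
18	MEF2D	100	55.05
19	DUSP7	100	54.88
20	SRXN1	0	54.87
21	OTUD4	0	54.77
22	RLIM	80	54.63
23	MTHFD1	100	54.56
24	FAM162A	100	54.32
25	TIPARP	100	54.10
26	PAM	100	53.98
27	CLUAP1	100	53.93
28	C11orf73	100	53.89
29	PEX19	100	53.61
30	ATF3	80	53.42
31	PRKAR2A	40	53.29
32	DUSP10	80	53.22
33	FOCAD	100	52.88
34	FAM213B	100	52.87
35	1562056_at	0	52.69
36	KIAA0232	40	52.26
37	CBX4	100	52.13
38	MRPS22	40	51.66
39	PHF17	40	51.64
40	SNX18	80	51.57
41	CGRRF1	100	51.47
42	ABHD13	40	51.46
43	GLT8D1	100	51.40
44	KIAA2018	40	51.32
45	MPPE1	40	51.29
46	GGNBP2	40	51.27
47	MOAP1	100	51.20
48	PTGER4	40	51.14
49	ZNF273	80	51.13
50	ENO2	20	50.98
51	HERPUD1	100	50.91
52	IKZF4	0	50.80
53	CGRRF1	100	50.77
54	231061_at	40	50.76
55	ARG2	100	50.72
56	CDS2	40	50.67
57	LPIN2	40	50.63
58	FAM162A	100	50.61
59	KLF4	100	50.55
60	TMEM18	60	50.46
61	FARS2	40	50.43
62	CEP57	100	50.26
63	APC	40	50.15
64	DPH5	80	50.14
65	LINC00909	40	50.08
66	IRS2	100	50.07
67	FLJ31306	20	49.91
68	SNRK	60	49.87
69	ZNF331	100	49.84
70	MRPS31	100	49.76
71	C11orf21	100	49.73
72	OSBPL7	100	49.72
73	ZSCAN16	40	49.72
74	FAM13A	100	49.71
75	ZNF764	40	49.59
76	CYP2R1	40	49.52
77	BCL11B	100	49.41
78	RNF113A	100	49.32
79	COA5	100	49.31
80	CITED2	100	49.22
81	RIPK2	40	49.06
82	EGR1	80	49.01
83	C1orf132	100	49.01
84	CD44	40	48.99
85	TM2D2	100	48.97
86	OXNAD1	100	48.90
87	DERA	100	48.87
88	PPIL3	100	48.84
89	SNX20	100	48.75
90	PEX19	100	48.63
91	ZNF331	100	48.63
92	C14orf166	100	48.63
93	FAM162A	100	48.63
94	SLC46A3	40	48.60
95	CD164	20	48.56
96	NRBF2	60	48.55
97	ZNF350	60	48.54
98	DERA	100	48.48
99	THEM4	100	48.47
100	ZMYM4	100	48.42
101	RPF1	100	48.39
102	CFLAR	0	48.36
103	PCYOX1	100	48.35
104	DUSP1	100	48.33
105	ACOX1	100	48.32
106	ING3	80	48.29
107	IRF1	100	48.23
108	PIK3R1	100	48.17
109	KLF6	80	48.14
110	NCOA7	40	48.09
111	BNIP3	100	48.08
112	SQRDL	100	48.04
113	S100A10	80	48.02
114	RNF6	40	48.02
115	RBBP6	100	48.01
116	ZADH2	100	47.98
117	KIF11	100	47.97
118	TGS1	0	47.95
119	SRSF7	100	47.79
120	MAPKAP1	100	47.62
121	KLF4	100	47.60
122	ZNF559	100	47.56
123	LPIN2	40	47.53
124	NPRL2	100	47.53
125	KIAA0391	100	47.53
126	TIPARP	100	47.52
127	ING3	80	47.37
128	CBX4	100	47.36
129	FOCAD	100	47.30
130	FAM63B	40	47.25
131	OSBPL2	40	47.18
132	DFFA	100	47.17
133	GCFC2	80	47.12
134	BCL11B	100	47.11
135	RLIM	100	47.09
136	229447_x_at	100	47.00
137	PCYOX1	100	46.99
138	R3HDM2	100	46.98
139	MKKS	100	46.96
140	HINT1	100	46.94
141	HERC4	100	46.84
142	ATPAF1	100	46.79
143	UGP2	100	46.79
144	BUD13	40	46.75
145	FAM213B	100	46.74
146	RPL34	20	46.60
147	CD33	100	46.60
148	203359_s_at	100	46.60
149	METTL5	100	46.53
150	217317_s_at	100	46.45
151	FAM13A	100	46.44
152	SLC35F6	0	46.42
153	DBR1	40	46.39
154	MAP1LC3B	20	46.39
155	ACYP2	0	46.35
156	NUDT15	100	46.34
157	PDE4D	80	46.33
158	GOLGB1	40	46.32
159	SETD7	100	46.31
160	NSMCE2	100	46.25
161	MORF4L1	80	46.16
162	CASP6	100	46.15
163	ATG2A	100	46.13
164	RBBP6	100	46.09
165	UBFD1	100	46.05
166	222021_x_at	100	46.05
167	KLF6	80	46.04
168	GDE1	80	45.99
169	KDM2A	80	45.98
170	FAM162A	100	45.93
171	GIMAP4	100	45.92
172	NCF2	100	45.91
173	DUSP7	100	45.90
174	MRPL39	40	45.88
175	COQ5	100	45.83
176	INPP4A	100	45.78
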