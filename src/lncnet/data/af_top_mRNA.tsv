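probe_id	gene_symbol	fc_abs	p	regulation	N1	N2	N3	AF1	AF2	AF3
NM_000559	HBG1	16.03	0.01	up	4.97	7.33	4.25	9.98	9.40	9.18
NM_000342	SLC4A1	14.84	0.00	up	3.15	4.55	2.77	7.31	6.75	8.09
NM_003944	SELENBP1	9.25	0.02	up	4.31	5.50	2.77	6.99	6.99	8.22
DQ656067	clone Affy2H6-6	8.66	0.02	up	4.87	6.87	4.49	8.68	8.77	8.11
NM_000519	HBD	6.24	0.02	up	14.37	15.04	12.74	16.55	16.53	16.99
NM_000517	HBA2	6.15	0.02	up	13.82	13.80	11.72	15.40	15.75	16.05
NM_004415	DSP	6.09	0.00	down	5.35	5.51	5.75	2.93	3.09	2.77
XM_003119591	uncharacterized LOC100508797	5.80	0.04	down	7.52	6.98	7.42	3.18	5.75	5.39
NM_007308	SNCA	5.76	0.01	up	10.48	10.84	9.37	12.80	12.44	13.04
NM_000518	HBB	5.75	0.03	up	15.36	15.64	13.28	17.22	17.09	17.54
NM_000032	ALAS2	4.88	0.04	up	6.45	8.03	5.64	8.44	9.55	8.99
AY172958	anti-rabies SOJB immunoglobulin heavy chain	4.87	0.03	down	10.42	10.10	11.64	7.39	9.17	8.75
NM_017414	USP18	4.60	0.01	down	7.63	6.71	6.10	4.15	5.01	4.67
HCG1981372		4.29	0.00	down	8.17	8.80	8.76	6.25	6.25	6.95
XM_003403505	Ig kappa chain V-III region VH-like	4.27	0.01	down	9.61	9.56	9.87	6.65	8.18	7.93
AY505570	Immunoglobulin heavy chain	4.22	0.00	down	9.56	9.36	10.13	7.16	8.09	7.57
A_33_P3331178		4.21	0.02	down	7.63	7.74	8.20	5.28	6.77	5.29
A_24_P110242		3.99	0.03	down	9.48	9.72	10.90	7.39	8.80	7.93
NM_002100	GYPB	3.93	0.00	up	3.44	3.56	3.67	5.33	5.53	5.73
XM_003403854	Ig heavy chain V-III region VH26-like	3.92	0.01	down	10.49	10.46	10.82	7.74	9.06	9.06
XM_003403466	Ig heavy chain V-I region V35-like	3.86	0.01	down	11.01	10.85	11.47	8.56	9.63	9.30
Z46771	Immunoglobulin heavy chain VDJ region	3.85	0.00	down	9.15	9.07	9.73	6.94	7.87	7.31
L03830	Ig rearranged H-chain mRNA V-region	3.84	0.01	down	8.62	8.70	8.86	6.21	7.50	6.66
Z18824	Rearranged Ig H-chain V-domain	3.83	0.01	down	8.56	8.75	9.56	6.46	7.65	6.95
AY393117	Clone RA702-M1-22.fa Immunoglobulin heavy chain	3.78	0.01	down	9.71	9.68	10.13	7.40	8.51	7.85
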