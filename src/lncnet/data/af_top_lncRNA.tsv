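probe_id	fc_abs	p	regulation	N1	N2	N3	AF1	AF2	AF3	chrom	start	end
NONHSAT098586	7.51	0.01	up	2.70	4.54	3.94	6.32	6.76	6.83	chr4	144918491	144940455
NONHSAG007503	7.34	0.02	up	12.37	12.85	10.51	14.53	14.51	15.32	chr11	5246697	5248302
NONHSAT040387	6.94	0.01	down	6.73	6.78	7.11	2.87	4.72	4.66	chr14	106068035	107099427
NONHSAT076398	6.80	0.00	up	3.80	2.82	2.83	6.03	5.92	5.78	chr2	202316456	202323546
NONHSAT053927	6.77	0.01	up	3.29	4.28	3.13	5.91	6.07	7.01	chr17	42338172	42345509
NONHSAT098582	6.55	0.03	up	4.55	5.13	2.63	6.81	6.40	7.23	chr4	144917349	144940477
NONHSAT040421	6.52	0.03	down	5.58	6.21	6.63	2.78	4.88	2.66	chr14	106329999	107034966
NONHSAT017667	6.00	0.02	up	15.01	15.47	13.18	17.10	16.87	17.43	chr11	5246884	5248053
TCONS_l2_00030433	5.25	0.00	down	7.66	8.28	8.29	5.06	5.70	6.29	chrX	3820106	3855883
NONHSAT039492	5.21	0.01	down	10.72	10.45	9.85	7.62	8.70	7.57	chr14	96177059	96178299
NONHSAT090718	5.15	0.04	up	5.35	3.08	3.59	6.91	6.67	5.53	chr3	93624883	93630001
NONHSAG053956	5.03	0.00	down	7.97	8.40	8.26	5.63	5.64	6.36	chrX	3735557	3785832
NONHSAT098591	4.92	0.00	up	4.05	3.48	3.56	5.95	5.77	6.26	chr4	145035828	145061788
NONHSAT136136	4.81	0.00	down	7.29	7.70	7.72	4.75	5.16	6.01	chrX	3735579	3785832
XR_245045.1	4.57	0.05	down	6.44	6.89	8.40	4.12	5.71	5.34			
NONHSAT141981	4.45	0.00	down	7.40	7.30	7.92	4.88	5.95	5.33	chr16	31973408	31985682
NONHSAT142052	4.42	0.02	down	5.80	5.91	6.57	3.03	4.67	4.16	chr16	32926394	32926857
NONHSAT076870	4.35	0.05	up	6.19	5.47	3.85	7.11	6.90	7.87	chr2	218678431	218680091
NONHSAT040390	4.32	0.00	down	10.72	10.84	11.13	8.30	9.24	8.81	chr14	106111027	106478375
ENST00000460164	4.18	0.03	down	13.24	12.64	13.65	9.98	11.83	11.51	14	106110833	106114892
ENST00000456563	4.10	0.00	down	8.76	9.10	9.22	6.43	7.09	7.46	X	3772390	3785176
NONHSAT040540	4.02	0.02	down	6.48	7.04	7.05	4.03	5.79	4.73	chr14	107108251	107108696
NONHSAT076401	3.98	0.00	up	5.85	5.87	5.55	7.86	7.45	7.95	chr2	202343864	202345071
NONHSAT136135	3.98	0.00	down	7.64	8.26	8.03	5.62	6.10	6.23	chrX	3735575	3742639
NONHSAT055019	3.95	0.03	up	4.35	2.68	2.68	5.42	4.76	5.47	chr17	57695918	57696926
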