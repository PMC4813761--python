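subject	condition	presented	unclassified	classified	change_fraction	fail_fraction	go_rt	fail_rt	success_rt	fail_soa	success_soa	ssrt_av	ssrt_mcmc	deviance	rejected
1	3	155	10	145	0.49	0.31	0.64	0.59	0.94	0.50	0.45	0.176	0.167	1.2	0
1	4	154	14	140	0.47	0.34	0.54	0.48	0.84	0.35	0.30	0.214	0.213	1.4	0
3	1	155	8	147	0.51	0.49	0.43	0.39		0.25	0.20	0.202	0.195	1.6	0
3	2	153	10	143	0.50	0.42	0.44	0.42		0.30	0.25	0.178	0.173	2.1	0
3	3	156	12	144	0.51	0.47	0.41	0.38	0.52	0.25	0.15	0.217	0.228	1.2	0
3	4	155	20	135	0.50	0.45	0.37	0.34	0.43	0.20	0.15	0.191	0.189	0.6	0
4	1	155	8	147	0.51	0.35	0.71	0.66		0.55	0.45	0.224	0.211	3.2	0
4	2	122	8	114	0.48	0.29	0.73	0.70		0.58	0.50	0.229	0.216	3.1	0
4	3	155	14	141	0.48	0.33	0.71	0.60	1.01	0.48	0.45	0.246	0.231	2.7	0
4	4	155	12	143	0.46	0.33	0.63	0.54	0.94	0.47	0.40	0.208	0.199	4.8	0
5	1	153	4	149	0.49	0.33	0.57	0.54		0.42	0.40	0.157	0.147	7.9	1
5	2	155	4	151	0.50	0.20	0.72	0.71		0.60	0.55				1
5	3	155	12	143	0.48	0.35	0.78	0.68	1.09	0.60	0.50	0.245	0.245	2.2	0
5	4	155	36	119	0.42	0.27	0.63	0.50	0.79	0.40	0.35				1
6	1	154	6	148	0.51	0.40	0.53	0.48		0.35	0.30	0.216	0.198	6.9	0
6	2	151	4	147	0.48	0.39	0.65	0.61		0.50	0.45	0.199	0.197	1.7	0
6	3	151	18	133	0.48	0.23	0.86	0.71	1.10	0.70	0.60				1
6	4	155	12	143	0.50	0.37	0.76	0.69	0.95	0.60	0.50	0.233	0.209	1.4	0
7	1	156	10	146	0.49	0.42	0.54	0.48		0.40	0.35	0.178	0.169	7.6	0
7	2	154	6	148	0.49	0.40	0.50	0.47		0.35	0.30	0.161	0.168	5.6	0
7	3	155	16	139	0.49	0.43	0.55	0.50	0.72	0.35	0.30	0.221	0.213	2.0	0
7	4	155	14	141	0.49	0.44	0.61	0.56	0.85	0.45	0.40	0.191	0.194	0.8	0
8	1	155	7	148	0.49	0.42	0.43	0.42		0.25	0.25	0.170	0.165	1.3	0
8	2	155	8	147	0.50	0.38	0.54	0.50		0.30	0.30	0.256	0.243	1.3	0
8	3	154	31	123	0.44	0.24	0.74	0.56	0.86	0.50	0.45				1
8	4	156	38	118	0.41	0.24	0.58	0.48	0.75	0.32	0.33				1
9	1	154	10	144	0.48	0.44	0.57	0.53		0.30	0.25	0.306	0.300	4.3	0
9	2	154	8	146	0.50	0.36	0.56	0.47		0.35	0.30	0.216	0.189	2.5	0
9	3	154	25	129	0.50	0.35	0.60	0.52	0.67	0.35	0.30	0.251	0.222	2.2	0
9	4	156	37	119	0.47	0.34	0.53	0.51	0.61	0.35	0.30	0.178	0.163	2.9	0
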