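pair_id	long_arm	short_arm	printed_ta	printed_ar	printed_ci	printed_ct
1	1.85	0.59	2.34	3.13	0.25	st
2	1.78	0.98	2.76	1.82	0.36	sm
3	1.55	0.70	2.25	2.21	0.31	sm
4	1.52	0.49	2.01	3.10	0.24	st
5	1.35	0.91	2.26	1.48	0.40	m
6	1.12	0.90	2.02	1.24	0.45	m
7	1.27	0.79	2.06	1.61	0.38	m
8	1.39	0.69	2.08	2.01	0.33	sm
9	1.34	0.66	2.00	2.03	0.33	sm
10	1.29	0.62	1.91	2.08	0.32	sm
11	1.39	0.62	2.01	2.24	0.31	sm
12	1.33	0.59	1.92	2.25	0.31	sm
13	1.59	0.50	2.09	3.11	0.24	st
14	1.23	0.69	1.92	1.78	0.36	sm
15	1.19	0.69	1.88	1.72	0.37	sm
16	1.35	0.62	1.97	2.18	0.31	sm
17	1.21	0.77	1.98	1.57	0.39	m
18	1.13	0.67	1.80	1.69	0.37	sm
19	1.18	0.74	1.92	1.59	0.39	m
20	1.07	0.79	1.86	1.35	0.42	m
21	1.04	0.63	1.67	1.65	0.38	m
22	1.04	0.68	1.72	1.53	0.40	m
23	0.95	0.62	1.57	1.53	0.39	m
24	1.06	0.56	1.62	1.89	0.35	sm
25	2.13	0.50	2.63	4.26	0.19	st
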