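pair_id	long_arm	short_arm	printed_ta	printed_ar	printed_ci	printed_ct
1	6.53	2.69	9.21	2.43	0.29	sm
2	5.72	2.51	8.22	2.28	0.30	sm
3	5.32	2.64	7.95	2.02	0.33	sm
4	5.48	2.11	7.58	2.60	0.28	sm
5	4.92	2.10	7.01	2.35	0.30	sm
6	4.64	2.29	6.94	2.03	0.33	sm
7	4.97	1.76	6.73	2.83	0.26	sm
8	4.43	2.28	6.71	1.94	0.34	sm
9	4.86	1.58	6.70	1.63	0.28	m
10	4.29	2.40	6.69	1.78	0.36	sm
11	4.36	2.30	6.69	1.91	0.34	sm
12	4.74	1.62	6.36	2.93	0.25	sm
13	4.57	1.74	6.31	2.63	0.28	sm
14	4.36	1.94	6.30	2.25	0.31	sm
15	4.57	1.61	6.18	2.85	0.26	sm
16	4.44	1.70	6.14	2.61	0.28	sm
17	4.62	1.46	6.08	3.16	0.24	st
18	4.32	1.65	5.97	2.62	0.28	sm
19	4.59	1.35	5.94	3.41	0.23	st
20	4.05	1.85	5.90	2.20	0.31	sm
21	4.33	1.54	5.86	2.82	0.26	sm
22	4.16	1.68	5.83	2.48	0.29	sm
23	3.69	1.70	5.36	2.15	0.32	sm
24	3.34	1.98	5.32	1.69	0.37	m
25	4.07	0.99	5.06	4.11	0.20	st
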