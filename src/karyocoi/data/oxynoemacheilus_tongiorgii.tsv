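pair_id	long_arm	short_arm	printed_ta	printed_ar	printed_ci	printed_ct
1	1.97	0.63	2.60	3.12	0.24	st
2	1.92	1.09	3.01	1.76	0.36	st
3	1.59	1.13	2.72	1.41	0.42	st
4	1.97	1.05	3.02	1.88	0.35	m
5	1.44	1.34	2.78	1.07	0.48	sm
6	1.78	0.93	2.71	1.91	0.34	m
7	1.59	0.82	2.41	1.94	0.34	sm
8	1.54	0.78	2.32	1.97	0.34	sm
9	1.59	0.80	2.39	1.99	0.33	m
10	1.51	0.82	2.33	1.84	0.35	sm
11	1.51	0.82	2.33	1.84	0.35	sm
12	1.99	0.60	2.59	3.31	0.23	sm
13	1.42	0.63	2.05	2.25	0.31	st
14	1.16	0.62	2.04	2.29	0.30	sm
15	1.22	0.76	1.92	1.53	0.40	sm
16	1.24	0.78	2.00	1.56	0.39	st
17	1.18	1.09	2.33	1.14	0.47	st
18	1.21	0.95	2.13	1.24	0.45	sm
19	1.20	1.00	2.21	1.21	0.45	sm
20	1.18	0.70	1.90	1.71	0.37	m
21	1.35	0.64	1.82	1.84	0.35	sm
22	0.94	0.74	2.09	1.82	0.35	m
23	1.05	0.79	1.73	1.19	0.49	st
24	1.05	0.66	1.71	1.59	0.39	sm
25	1.58	0.42	2.00	3.76	0.21	sm
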