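record	total_beats	tp	fn	fp	sen	pos_pred	acc
100	2273	2273	0	0	100.00	100.00	100.00
101	1865	1864	1	1	99.95	99.95	99.89
102	2187	2187	0	0	100.00	100.00	100.00
103	2084	2084	0	0	100.00	100.00	100.00
104	2229	2222	7	10	99.69	99.55	99.24
105	2572	2528	44	50	98.29	98.06	96.41
106	2027	2004	23	22	98.87	98.91	97.80
107	2137	2121	16	6	99.25	99.72	98.97
108	1763	1739	24	18	98.64	98.98	97.64
109	2532	2532	0	0	100.00	100.00	100.00
111	2124	2117	7	4	99.67	99.81	99.48
112	2539	2539	0	0	100.00	100.00	100.00
113	1795	1795	0	0	100.00	100.00	100.00
114	1879	1872	7	10	99.63	99.47	99.10
115	1953	1953	0	0	100.00	100.00	100.00
116	2412	2393	19	5	99.21	99.79	99.01
117	1535	1534	1	1	99.93	99.93	99.87
118	2278	2277	1	0	99.96	100.00	99.96
119	1987	1987	0	0	100.00	100.00	100.00
121	1863	1860	3	3	99.84	99.84	99.68
122	2476	2476	0	0	100.00	100.00	100.00
123	1518	1518	0	0	100.00	100.00	100.00
124	1619	1617	2	2	99.88	99.88	99.75
200	2601	2593	8	3	99.69	99.88	99.58
201	1963	1962	1	1	99.95	99.95	99.90
202	2136	2123	13	6	99.39	99.72	99.11
203	2980	2953	27	21	99.09	99.29	98.40
205	2656	2640	16	2	99.40	99.92	99.32
207	2332	2018	314	328	86.54	86.02	75.86
208	2955	2932	23	3	99.22	99.90	99.12
209	3005	3005	0	1	100.00	99.97	99.97
210	2650	2629	21	13	99.21	99.51	98.72
212	2748	2748	0	0	100.00	100.00	100.00
213	3251	3245	6	2	99.82	99.94	99.75
214	2262	2253	9	10	99.60	99.56	99.16
215	3363	3360	3	4	99.91	99.88	99.79
217	2208	2193	15	10	99.32	99.55	98.87
219	2154	2154	0	0	100.00	100.00	100.00
220	2048	2048	0	0	100.00	100.00	100.00
221	2427	2417	10	5	99.59	99.79	99.38
222	2483	2480	3	3	99.88	99.88	99.76
223	2605	2585	20	0	99.23	100.00	99.23
228	2053	2032	21	14	98.98	99.32	98.31
230	2256	2256	0	0	100.00	100.00	100.00
231	1571	1571	0	0	100.00	100.00	100.00
232	1780	1778	2	2	99.89	99.89	99.78
233	3079	3078	1	1	99.97	99.97	99.94
234	2753	2753	0	0	100.00	100.00	100.00
Total	109966	109298	668	561	99.39	99.49	98.89
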