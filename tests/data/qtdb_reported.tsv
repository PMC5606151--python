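record	total_beats	tp	fn	fp	sen	pos_pred	acc
sel100	1134	1134	0	0	100.00	100.00	100.00
sel102	1088	1088	0	0	100.00	100.00	100.00
sel103	1048	1048	0	0	100.00	100.00	100.00
sel104	1109	1109	0	1	100.00	99.91	99.91
sel114	862	858	4	8	99.54	99.08	98.62
sel116	1185	1184	1	1	99.92	99.92	99.83
sel117	766	766	0	0	100.00	100.00	100.00
sel123	756	756	0	0	100.00	100.00	100.00
sel213	1642	1636	6	1	99.63	99.94	99.57
sel221	1247	1240	7	3	99.44	99.76	99.20
sel223	1309	1307	2	2	99.85	99.85	99.69
sel230	1077	1077	0	0	100.00	100.00	100.00
sel231	732	732	0	0	100.00	100.00	100.00
sel232	865	864	1	0	99.88	100.00	99.88
sel233	1533	1507	26	1	98.30	99.93	98.24
sel301	1351	1346	5	1	99.63	99.93	99.56
sel302	1500	1498	2	1	99.87	99.93	99.80
sel306	1040	1040	0	0	100.00	100.00	100.00
sel307	853	853	0	0	100.00	100.00	100.00
sel308	1294	1285	9	5	99.30	99.61	98.92
sel310	2012	1997	15	2	99.25	99.90	99.16
sel803	1026	1026	0	0	100.00	100.00	100.00
sel808	903	902	1	1	99.89	99.89	99.78
sel811	704	704	0	0	100.00	100.00	100.00
sel820	1159	1158	1	0	99.91	100.00	99.91
sel821	1557	1556	1	1	99.94	99.94	99.87
sel840	1180	1179	1	0	99.92	100.00	99.92
sel847	801	801	0	0	100.00	100.00	100.00
sel853	1113	1113	0	0	100.00	100.00	100.00
sel871	917	917	0	0	100.00	100.00	100.00
sel872	990	990	0	0	100.00	100.00	100.00
sel873	859	858	1	1	99.88	99.88	99.77
sel883	892	891	1	2	99.89	99.78	99.66
sel891	1267	1266	1	0	99.92	100.00	99.92
sel14046	1260	1260	0	0	100.00	100.00	100.00
sel14157	1081	1081	0	0	100.00	100.00	100.00
sel14172	663	663	0	0	100.00	100.00	100.00
sel15814	1036	1035	1	0	99.90	100.00	99.90
sel16265	1031	1031	0	0	100.00	100.00	100.00
sel16272	851	851	0	0	100.00	100.00	100.00
sel16273	1112	1111	1	0	99.91	100.00	99.91
sel16420	1063	1063	0	0	100.00	100.00	100.00
sel16483	1087	1087	0	0	100.00	100.00	100.00
sel16539	922	922	0	0	100.00	100.00	100.00
sel16773	1008	1007	1	0	99.90	100.00	99.90
sel16786	925	925	0	0	100.00	100.00	100.00
sel16795	761	761	0	0	100.00	100.00	100.00
sel17152	1628	1628	0	0	100.00	100.00	100.00
sel17453	1047	1047	0	0	100.00	100.00	100.00
sele0104	804	804	0	0	100.00	100.00	100.00
sele0106	896	896	0	0	100.00	100.00	100.00
sele0107	812	806	6	2	99.26	99.75	99.02
sele0110	872	870	2	9	99.77	98.98	98.75
sele0111	907	907	0	0	100.00	100.00	100.00
sele0112	684	675	9	12	98.68	98.25	96.98
sele0114	699	698	1	1	99.86	99.86	99.71
sele0116	558	558	0	0	100.00	100.00	100.00
sele0121	1436	1431	5	0	99.65	100.00	99.65
sele0122	1415	1415	0	0	100.00	100.00	100.00
sele0124	1121	1121	0	0	100.00	100.00	100.00
sele0126	945	945	0	1	100.00	99.89	99.89
sele0129	671	644	27	23	95.98	96.55	92.80
sele0133	840	840	0	0	100.00	100.00	100.00
sele0136	809	809	0	0	100.00	100.00	100.00
sele0166	813	813	0	0	100.00	100.00	100.00
sele0170	897	897	0	2	100.00	99.78	99.78
sele0203	1246	1245	1	1	99.92	99.92	99.84
sele0210	1063	1062	1	0	99.91	100.00	99.91
sele0211	1575	1573	2	4	99.87	99.75	99.62
sele0303	1045	1044	1	0	99.90	100.00	99.90
sele0405	1216	1216	0	1	100.00	99.92	99.92
sele0406	959	959	0	1	100.00	99.90	99.90
sele0409	1737	1737	0	0	100.00	100.00	100.00
sele0411	1202	1202	0	0	100.00	100.00	100.00
sele0509	1028	1028	0	0	100.00	100.00	100.00
sele0603	870	869	1	0	99.89	100.00	99.89
sele0604	1031	1031	0	0	100.00	100.00	100.00
sele0606	1442	1442	0	0	100.00	100.00	100.00
sele0607	1184	1184	0	0	100.00	100.00	100.00
sele0609	1127	1125	2	2	99.82	99.82	99.65
sele0612	751	751	0	0	100.00	100.00	100.00
sele0704	1094	1093	1	1	99.91	99.91	99.82
Total	86995	86848	147	91	99.83	99.90	99.73
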