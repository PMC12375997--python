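table	gene_scope	label	al_a	al_n	mm_a	mm_n	oas_a	oas_n	or_al_mm	or_al_oas
1	ALL_KV	X37D	11	192	26	590	84902	4288405	1.3	2.9
1	ALL_KV	X51N	18	192	30	595	136197	4295181	1.9	3
1	ALL_KV	X76V	1	192	1	595	31514	4295181	3.1	0.78
1	ALL_KV	X83Y	3	192	7	588	133634	4264717	1.3	0.51
1	ALL_KV	X86N	27	192	14	595	36580	4295181	6	17
1	ALL_KV	X88N	11	192	8	595	24123	4295181	4.2	10
1	ALL_KV	ST20X	19	192	35	590	192697	4288405	1.7	2.2
1	ALL_KV	I29X	16	146	47	364	129106	1585731	0.85	1.4
1	ALL_KV	P72X	20	192	13	595	183142	4295181	4.8	2.5
1	ALL_KV	ST74X	18	146	25	359	81049	1578955	1.8	2.4
1	ALL_KV	R75X	15	169	8	590	124890	4235271	6.5	3
1	ALL_KV	P96X	19	151	22	470	207638	2578061	2.7	1.6
1	ALL_KV	D98X	3	192	2	595	95042	4295181	4.6	0.73
1	ALL_KV	Q106X	11	191	39	588	413149	4232213	0.87	0.59
2	IGKV1-16	R75N	7	23	0	5	1428	59910	16	13
2	IGKV1-33	Y38H	6	68	6	132	5346	166773	1.9	2.8
2	IGKV1-33	Y38S	4	68	13	132	5538	166773	0.61	1.8
2	IGKV1-33	N40I	6	68	5	132	1352	166773	2.3	11
2	IGKV1-33	P46L	2	68	1	132	813	166773	3.7	6.3
2	IGKV1-33	K48Q	4	68	4	132	2857	166773	1.9	3.5
2	IGKV1-33	K51N	9	68	9	132	7541	166773	1.9	3
2	IGKV1-33	S79R	4	68	3	132	4356	166773	2.6	2.3
2	IGKV1-33	D86E	2	68	3	132	6632	166773	1.3	0.77
2	IGKV1-33	D86H	11	68	23	132	12679	166773	0.93	2.1
2	IGKV1-33	D86N	15	68	4	132	3161	166773	7.1	12
2	IGKV1-33	Y103H	3	68	0	132	1281	166773	60	5.9
2	IGKV1-33	P115PP	6	68	14	132	27844	166773	0.84	0.54
2	IGKV1-33	Y116Q	1	68	1	132	1794	166773	1.9	1.5
2	IGKV1-39	S28T	7	30	9	44	37334	529242	1.1	3.3
2	IGKV1-39	S36R	2	30	1	44	23091	529242	2.8	1.6
2	IGKV1-39	Y55F	6	30	2	44	19960	529242	4.3	5.4
2	IGKV1-5	P46X	1	14	4	102	14875	375689	1.9	2
2	IGKV1-5	K56DE	2	14	19	102	48945	375689	0.79	1.1
2	IGKV4-1	L15P	2	22	1	28	5063	510939	2.4	9.5
2	IGKV4-1	N34F	1	22	0	28	245	510939	14	100
2	IGKV4-1	K36T	1	22	0	28	2437	510939	14	10
2	IGKV4-1	P46L	1	22	0	28	3284	510939	14	7.7
2	IGKV4-1	Y116P	7	22	3	28	43825	510939	2.9	3.7
2	IGKV4-1	Y116Q	3	22	1	28	19195	510939	3.6	3.7
3	IGLV1-44	A100T	1	77	3	42	3158	338214	0.19	1.5
3	IGLV1-51	G84D	0	32	0	19	9150	186959	0.6	0.063
3	IGLV2-14	L94V	1	90	0	42	3617	652830	5.1	2.2
3	IGLV3-19	G56R	1	17	0	16	1118	151676	10	8.7
3	IGLV3-19	G113A	2	17	1	16	2012	151676	1.8	9.2
3	IGLV6-57	F2X	4	137	3	9	4844	90110	0.089	0.56
3	IGLV6-57	R25G	33	137	0	9	5958	90110	22	3.6
3	IGLV6-57	N37T	5	137	0	9	7587	90110	3.4	0.44
3	IGLV6-57	G70E	2	137	0	9	2798	90110	1.4	0.49
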