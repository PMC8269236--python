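pathway_id	family_id	core_count	full_count	arCOG	COG	eggNOG	KEGG
precorrin2	cobA	3183	10596	22	24	604	65
precorrin2	hemA	18014	21723	64	75	1590	172
precorrin2	hemB	5243	13701	8	17	256	33
precorrin2	hemC	21924	28373	57	61	1487	202
precorrin2	hemD	5	26	NA	NA	2	0
precorrin2	hemL	23309	29979	39	51	973	162
precorrin2	cysG	577	3654	3	4	91	25
precorrin2	gltX	35259	46056	88	92	2134	251
aerobic	cobB	2231	5182	10	17	571	64
aerobic	cobC-beta	85	1260	1	0	20	4
aerobic	cobD	142	696	2	3	15	6
aerobic	cobF	282	1580	NA	1	8	1
aerobic	cobG	80	443	NA	0	14	4
aerobic	cobH	958	3192	2	7	73	20
aerobic	cobI	628	2910	3	7	75	14
aerobic	cobJ	1138	4027	6	9	209	15
aerobic	cobK	405	2444	1	5	88	16
aerobic	cobL	590	3139	4	9	131	27
aerobic	cobM	1975	4619	2	6	101	18
aerobic	cobN	328	2987	2	8	234	26
aerobic	cobO	1167	3764	0	4	36	4
aerobic	cobP	364	3133	1	4	41	9
aerobic	cobQ	4815	9823	25	53	692	97
aerobic	cobR	1	8	NA	NA	1	NA
aerobic	cobS-co	269	1394	NA	0	14	2
aerobic	cobT-co	210	1437	3	2	59	4
anaerobic	cobA	3183	10596	22	24	604	65
anaerobic	cobD	142	696	2	3	15	6
anaerobic	cobU-ade	441	1305	1	0	15	0
anaerobic	cbiA	3282	5293	3	17	349	50
anaerobic	cbiB	273	900	0	0	2	0
anaerobic	cbiC	80	986	0	0	7	3
anaerobic	cbiD	7485	9637	32	43	673	113
anaerobic	cbiE	30	244	0	1	2	1
anaerobic	cbiF	472	655	1	5	42	11
anaerobic	cbiG	401	827	1	0	8	2
anaerobic	cbiH	10	423	1	5	9	4
anaerobic	cbiJ	33	100	0	0	2	0
anaerobic	cbiK	196	230	1	1	7	1
anaerobic	cbiL	164	252	0	0	5	0
anaerobic	cbiP	1	1	NA	0	0	0
anaerobic	cbiT	377	939	1	0	23	7
anaerobic	cbiX	339	1285	4	5	43	8
anaerobic	btuR	14	32	0	0	3	1
anaerobic	pduX	61	131	NA	0	2	0
salvage_remodeling	btuB	1857	2328	NA	8	66	10
salvage_remodeling	btuC	1610	2292	8	11	297	41
salvage_remodeling	btuD	1486	2232	22	49	139	115
salvage_remodeling	btuF	1616	2427	1	2	53	12
salvage_remodeling	cobA	3183	10596	22	24	604	65
salvage_remodeling	cobO	1167	3764	0	4	36	4
salvage_remodeling	cobP	364	3133	1	4	41	9
salvage_remodeling	cobU-ade	441	1305	1	0	15	0
salvage_remodeling	cobY	9	81	0	0	0	0
salvage_remodeling	cbiB	273	900	0	0	2	0
salvage_remodeling	cbiZ	13	105	1	1	2	1
salvage_remodeling	eutT	64	127	NA	0	6	0
salvage_remodeling	pduO	134	885	0	2	10	2
post_adocbip	cobC-ado	53	142	1	2	4	8
post_adocbip	cobP	364	3133	1	4	41	9
post_adocbip	cobS-gdp	12009	25088	176	77	3921	322
post_adocbip	cobT-alpha	11555	20236	52	76	2252	215
post_adocbip	cobU-alpha	1	4	NA	NA	0	0
post_adocbip	cobU-ade	441	1305	1	0	15	0
post_adocbip	cobV	1	2	NA	NA	0	0
post_adocbip	pduS	1	217	NA	1	2	1
post_adocbip	pduO	134	885	0	2	10	2
post_adocbip	fre	56	77	NA	1	5	3
post_adocbip	ubiB	1	1	NA	NA	NA	NA
post_adocbip	bluB	1323	2101	1	4	78	16
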