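id	gene_name	glean_id	gene_length	transcript_length	protein_length	protein_mw	chromosome	start	end
1	PgPIP1-1	Pgl_GLEAN_10001520	3097	867	288	30.70	3	5721622	5724718
2	PgPIP1-3	Pgl_GLEAN_10010809	1601	867	288	30.76	3	274573998	274575598
3	PgPIP1-4	Pgl_GLEAN_10005724	992	900	298	31.38	2	104247932	104248932
4	PgPIP2-1	Pgl_GLEAN_10028064	2920	873	290	30.35	3	12453415	12456334
5	PgPIP2-2	Pgl_GLEAN_10028876	2830	867	288	30.12	3	45603209	45606038
6	PgPIP2-3	Pgl_GLEAN_10035675	1903	873	290	30.39	3	257669631	257671533
7	PgPIP2-5	Pgl_GLEAN_10028056	1062	834	277	28.93	3	12167791	12168852
8	PgPIP2-6	Pgl_GLEAN_10028055	1053	861	286	29.94	3	12156953	12158005
9	PgPIP2-7	Pgl_GLEAN_10010255	1170	861	286	29.79	Scaffold763	240584	241753
10	PgPIP2-8	Pgl_GLEAN_10009812	837	837	278	29.17	2	64966663	64967453
11	PgTIP1-1	Pgl_GLEAN_10002147	1499	750	249	25.72	5	153303973	153305471
13	PgTIP2-1	Pgl_GLEAN_10000631	844	744	247	24.88	2	30657555	30658398
16	PgTIP2-2	Pgl_GLEAN_10030617	933	747	248	25.03	3	100540239	100541171
12	PgTIP2-3	Pgl_GLEAN_10009584	851	750	249	25.06	3	33622445	33623295
15	PgTIP3-1	Pgl_GLEAN_10028702	911	801	266	27.41	2	44624536	44625481
14	PgTIP4-1	Pgl_GLEAN_10002901	2557	738	245	25.58	1	263875434	263878070
18	PgTIP4-2	Pgl_GLEAN_10003219	1455	744	247	25.15	3	148813464	148814777
17	PgTIP4-3	Pgl_GLEAN_10003218	844	747	248	25.10	3	148807632	148808412
19	PgTIP5-1	Pgl_GLEAN_10033583	1087	813	270	26.69	3	272599938	272601028
20	PgNIP1-1	Pgl_GLEAN_10012175	2316	846	281	29.52	2	195368171	195370486
21	PgNIP1-2	Pgl_GLEAN_10028618	2560	846	281	29.53	1	261387113	261389753
22	PgNIP1-4	Pgl_GLEAN_10028339	1137	837	278	29.36	3	145385690	145386826
23	PgNIP2-1	Pgl_GLEAN_10018521	3364	891	296	31.82	3	14105646	14109009
24	PgNIP2-2	Pgl_GLEAN_10019286	3821	894	297	31.57	2	103033018	103036838
25	PgNIP3-1	Pgl_GLEAN_10034621	3855	909	302	31.43	2	40497062	40500916
26	PgNIP3-2	Pgl_GLEAN_10030882	1151	846	281	29.60	4	55609410	55610656
27	PgNIP3-3	Pgl_GLEAN_10030883	1087	780	259	27.05	4	55648949	55650374
28	PgNIP3-4	Pgl_GLEAN_10030881	1258	750	249	25.15	4	55573901	55575272
29	PgNIP3-5	Pgl_GLEAN_10030872	934	837	278	27.79	4	55508562	55509419
30	PgNIP4-1	Pgl_GLEAN_10012100	1319	921	306	31.52	6	110090448	110091766
31	PgSIP1-1	Pgl_GLEAN_10003744	2818	726	241	25.32	1	175152169	175154986
32	PgSIP1-2	Pgl_GLEAN_10014008	3375	759	252	25.91	4	93394125	93397493
33	PgSIP2-1	Pgl_GLEAN_10026167	1899	759	252	27.10	5	126489209	126491163
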