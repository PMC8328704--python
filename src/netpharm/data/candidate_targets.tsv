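no	gene	protein_name	betweenness	closeness	degree
1	NTRK1	Neurotrophic receptor tyrosine kinase 1	0.05711884	0.56600852	1199
2	TP53	Tumor protein p53	0.02958689	0.5339014	768
3	APP	Amyloid-beta precursor protein	0.04325808	0.53585828	746
4	CUL3	Cullin 3	0.01621362	0.52767084	744
5	EGFR	Epidermal growth factor receptor	0.03631785	0.53435673	738
6	MCM2	Minichromosome maintenance complex component 2	0.01374128	0.52022299	639
7	ESR1	Estrogen receptor 1	0.01715955	0.52376403	634
8	XPO1	Exportin 1	0.02022198	0.52090261	631
9	FN1	Fibronectin 1	0.01700008	0.51837844	612
10	UBC	Ubiquitin C	0.01612385	0.52282751	583
11	CDK2	Cyclin-dependent kinase 2	0.01028813	0.50905292	554
12	COPS5	COP9 signalosome subunit 5	0.00808418	0.51083159	517
13	CUL7	Cullin 7	0.0048695	0.50431183	515
14	HSP90AA1	Heat shock protein 90 alpha family class A member 1	0.0130468	0.5220807	510
15	GRB2	Growth factor receptor bound protein 2	0.01540288	0.51268264	485
16	RNF2	Ring finger protein 2	0.00618846	0.4979564	484
17	MYC	V-myc avian myelocytomatosis viral oncogene homolog	0.01293694	0.50705202	482
18	SIRT7	Sirtuin 7	0.00526073	0.49220065	470
19	CUL1	Cullin 1	0.00576927	0.50257821	469
20	YWHAZ	Tyrosine 3-monooxygenase/tryptophan 5-monooxygenase activation protein zeta	0.00881384	0.51503053	466
21	OBSL1	Obscurin-like 1	0.00370032	0.49442002	454
22	CAND1	Cullin-associated and neddylation dissociated 1	0.00443969	0.49280899	450
23	NPM1	Nucleophosmin	0.00555129	0.51059371	447
24	ITGA4	Integrin subunit alpha 4	0.00477184	0.49671574	444
25	VCP	Valosin-containing protein	0.00713559	0.51005931	413
26	CCDC8	Coiled-coil domain containing 8	0.00480319	0.49453151	412
28	EP300	E1A binding protein p300	0.00792101	0.50367478	410
27	HSP90AB1	Heat shock protein 90 alpha family class B member 1	0.00696006	0.51089109	410
29	VCAM1	Vascular cell adhesion molecule 1	0.0048008	0.4901654	404
30	CDC5L	Cell division cycle 5 like	0.00445741	0.4891268	399
31	FBXO6	F-box protein 6	0.00660866	0.4884731	393
32	BRCA1	BRCA1, DNA repair associated	0.00689339	0.49897611	391
33	TRAF6	TNF receptor-associated factor 6	0.00575486	0.49914647	378
34	HNRNPU	Heterogeneous nuclear ribonucleoprotein U	0.00359109	0.49694086	371
35	SNW1	SNW domain containing 1	0.00370573	0.49164892	370
36	HDAC1	Histone deacetylase 1	0.00504406	0.48798398	362
37	EED	Embryonic ectoderm development	0.00288746	0.47673913	359
38	HUWE1	HECT, UBA, and WWE domain containing 1, E3 ubiquitin protein ligase	0.00326087	0.49508974	358
39	EWSR1	EWS RNA binding protein 1	0.00617052	0.49931694	356
40	HNRNPA1	Heterogeneous nuclear ribonucleoprotein A1	0.00376562	0.49660326	352
41	MDM2	MDM2 proto-oncogene	0.0054897	0.49744811	346
42	UBE2I	Ubiquitin conjugating enzyme E2 I	0.00515795	0.4938077	344
43	YWHAQ	Tyrosine 3-monooxygenase/tryptophan 5-monooxygenase activation protein theta	0.00453158	0.49643463	338
47	RPA1	Replication protein A1	0.00447185	0.4904943	329
46	VHL	Von Hippel-Lindau tumor suppressor	0.0044112	0.49126344	329
44	PARK2	Parkin RBR E3 ubiquitin protein ligase	0.00331119	0.48923592	329
45	HSPA5	Heat shock protein family A (Hsp70) member 5	0.002573	0.50292398	329
48	HDAC5	Histone deacetylase 5	0.00203062	0.48282695	327
49	HIST1H3E	Histone cluster 1 H3 family member e	0.00117386	0.4791348	320
50	HIST1H3B	Histone cluster 1 H3 family member b	0.00117386	0.4791348	320
51	HIST1H3G	Histone cluster 1 H3 family member g	0.00117386	0.4791348	320
52	HIST1H3C	Histone cluster 1 H3 family member c	0.00117386	0.4791348	320
53	HIST1H3H	Histone cluster 1 H3 family member h	0.00117386	0.4791348	320
54	HIST1H3J	Histone cluster 1 H3 family member j	0.00117386	0.4791348	320
55	HIST1H3A	Histone cluster 1 H3 family member a	0.00117386	0.4791348	320
56	HIST1H3D	Histone cluster 1 H3 family member d	0.00117386	0.4791348	320
57	HIST1H3I	Histone cluster 1 H3 family member i	0.00117386	0.4791348	320
58	HIST1H3F	Histone cluster 1 H3 family member f	0.00117386	0.4791348	320
59	HSPB1	Heat shock protein family B (small) member 1	0.00950276	0.49475465	319
60	HSPA8	Heat shock protein family A (Hsp70) member 8	0.00598969	0.50361695	312
61	SRC	SRC proto-oncogene, non-receptor tyrosine kinase	0.00389245	0.50017106	312
62	RPA2	Replication protein A2	0.00253078	0.48961822	310
63	CUL2	Cullin 2	0.00217148	0.48171334	309
64	CTNNB1	Catenin beta 1	0.00495783	0.5011426	304
65	EEF1A1	Eukaryotic translation elongation factor 1 alpha 1	0.00334497	0.49660326	304
66	YWHAG	Tyrosine 3-monooxygenase/tryptophan 5-monooxygenase activation protein gamma	0.00349418	0.49570524	300
67	AKT1	AKT serine/threonine kinase 1	0.00665037	0.49682827	296
68	AR	Androgen receptor	0.00533699	0.49264293	294
70	CREBBP	CREB binding protein	0.00344521	0.47960634	292
69	U2AF2	U2 small nuclear RNA auxiliary factor 2	0.00188521	0.4802365	292
71	IKBKG	Inhibitor of nuclear factor kappa B kinase subunit gamma	0.00421812	0.49126344	291
72	MAPK1	Mitogen-activated protein kinase 1	0.00590832	0.493086	287
73	YWHAE	Tyrosine 3-monooxygenase/tryptophan 5-monooxygenase activation protein epsilon	0.00319492	0.49253229	283
74	PAN2	PAN2 poly(A) specific ribonuclease subunit	0.00154999	0.46525936	281
75	SUZ12	SUZ12 polycomb repressive complex 2 subunit	0.00168493	0.46605037	279
76	IKBKE	Inhibitor of nuclear factor kappa B kinase subunit epsilon	0.00234006	0.47493232	276
77	ARRB2	Arrestin beta 2	0.00295499	0.48351891	274
78	CUL5	Ccullin 5	0.00161801	0.47421343	274
79	FUS	FUS RNA binding protein	0.00199535	0.48673843	271
80	SMURF1	SMAD specific E3 ubiquitin protein ligase 1	0.00239525	0.48288011	270
81	RPA3	Replication protein A3	0.00151664	0.47575659	268
82	STAU1	Staufen double-stranded RNA binding protein 1	0.00121324	0.47908247	261
83	RELA	RELA proto-oncogene, NF-kB subunit	0.00499948	0.48700866	260
84	GSK3B	Glycogen synthase kinase 3 beta	0.00641109	0.48641455	256
85	SMAD3	SMAD family member 3	0.00358228	0.48956357	255
86	BMI1	BMI1 proto-oncogene, polycomb ring finger	0.00156804	0.46619898	254
87	COMMD3-BMI1	COMMD3-BMI1 readthrough	0.00156804	0.46619898	254
88	BAG3	BCL2-associated athanogene 3	0.00385077	0.47819451	252
89	YWHAB	Tyrosine 3-monooxygenase/tryptophan 5-monooxygenase activation protein beta	0.00260668	0.48722506	250
90	HSPA4	Heat shock protein family A (Hsp70) member 4	0.00289896	0.49548125	248
91	PARP1	Poly(ADP-ribose) polymerase 1	0.00322874	0.48086833	247
92	SMAD2	SMAD family member 2	0.00305262	0.48002627	246
93	RPS27A	Ribosomal protein S27a	0.00243271	0.4884731	246
94	FLNA	Filamin A	0.00324118	0.4884731	245
95	MYH9	Myosin heavy chain 9	0.00289354	0.48673843	244
96	CDKN1A	Cyclin-dependent kinase inhibitor 1A	0.00408751	0.48123766	241
98	ACTB	Actin beta	0.00348475	0.49325236	238
97	TARDBP	TAR DNA binding protein	0.000956	0.47436729	238
99	HDAC2	Histone deacetylase 2	0.00315062	0.47055037	236
100	ABL1	ABL proto-oncogene 1, nonreceptor tyrosine kinase	0.00149438	0.49076871	236
101	CUL4B	Cullin 4B	0.00369003	0.47788189	234
102	FYN	FYN proto-oncogene, Src family tyrosine kinase	0.00105834	0.46619898	234
103	EZH2	Enhancer of zeste 2 polycomb repressive complex 2 subunit	0.00157335	0.46884019	233
104	CRK	CRK proto-oncogene, adaptor protein	0.00664489	0.48218997	232
105	PRKCA	Protein kinase C alpha	0.00314723	0.47971125	232
107	ARRB1	Arrestin beta 1	0.00432736	0.48018393	231
106	JUN	Jun proto-oncogene, AP-1 transcription factor subunit	0.00304336	0.47762169	231
108	TUBB	Tubulin beta class I	0.00214432	0.49464306	231
109	HNRNPK	Heterogeneous nuclear ribonucleoprotein K	0.00139431	0.48787542	230
110	RPL10	Ribosomal protein L10	0.0011806	0.46314678	229
112	CLTC	Clathrin heavy chain	0.00232751	0.48652246	228
111	FBXW11	F-box and WD repeat domain containing 11	0.00221635	0.47298609	228
113	HLA-B	Major histocompatibility complex, class I, B	0.00338256	0.45549901	227
114	PRKDC	Protein kinase, DNA-activated, catalytic polypeptide	0.00185628	0.48950893	227
115	BTRC	Beta-transducin repeat-containing E3 ubiquitin protein ligase	0.00175312	0.47793397	227
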