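mol_id	name	herb	OB	DL
MOL000211	Mairin	AR	55.38	0.78
MOL000239	Jaranol	AR	50.83	0.29
MOL000296	Hederagenin	AR	36.91	0.75
MOL000033	(3S,8S,9S,10R,13R,14S,17R)-10,13-Dimethyl-17-[(2R,5S)-5-propan-2-yloctan-2-yl]-2,3,4,7,8,9,11,12,14,15,16,17-dodecahydro-1H-cyclopenta[a]phenanthren-3-ol	AR	36.23	0.78
MOL000354	Isorhamnetin	AR	49.6	0.31
MOL000371	3,9-di-O-Methylnissolin	AR	53.74	0.48
MOL000374	5'-Hydroxyiso-muronulatol-2',5'-di-O-glucoside	AR	41.72	0.69
MOL000379	9,10-Dimethoxypterocarpan-3-O-beta-D-glucoside	AR	36.74	0.92
MOL000380	(6aR,11aR)-9,10-Dimethoxy-6a,11a-dihydro-6H-benzofurano[3,2-c]chromen-3-ol	AR	64.26	0.42
MOL000387	Bifendate	AR	31.1	0.67
MOL000392	Formononetin	AR	69.67	0.21
MOL000398	Isoflavanone	AR	109.99	0.3
MOL000417	Calycosin	AR	47.75	0.24
MOL000422	Kaempferol	AR	41.88	0.24
MOL000433	FA	AR	68.96	0.71
MOL000438	(3R)-3-(2-Hydroxy-3,4-dimethoxyphenyl)chroman-7-ol	AR	67.67	0.26
MOL000439	Isomucronulatol-7,2'-di-O-glucosiole	AR	49.28	0.62
MOL000442	1,7-Dihydroxy-3,9-dimethoxy pterocarpene	AR	39.05	0.48
MOL001792	DFV	PN	32.76	0.18
MOL001494	Mandenol	PN	42	0.19
MOL007475	Ginsenoside F2	PN	36.43	0.25
MOL002879	Diop	PN	43.59	0.39
MOL005344	Ginsenoside Rh2	PN	36.32	0.56
MOL000358	Beta-sitosterol	PN	36.91	0.75
MOL000449	Stigmasterol	PN	43.83	0.76
MOL000098	Quercetin	AR+PN	46.43	0.28
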