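target	pdb_id	Quercetin	Kaempferol	Isorhamnetin	Formononetin
MAPK1	4iz5	-8.4	-8.4	-8.4	-8.0
AKT1	1unq	-6.4	-6.0	-6.3	-6.6
GSK3B	4afj	-8.3	-8.4	-8.4	-7.6
CDKN1A	2zvw	-7.5	-7.5	-7.5	-7.4
TP53	2k8f	-6.9	-6.4	-6.7	-7.4
RELA	1nfi	-7.7	-8.5	-8.6	-8.3
MYC	5g1x	-7.9	-7.9	-7.5	-7.5
GRB2	1gri	-7.5	-7.6	-7.7	-7.6
JUN	1s9k	-8.6	-9.7	-9.7	-8.3
EGFR	5wb7	-7.7	-7.9	-8.0	-8.0
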