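proband	chrom	pos	ref	alt	gene	transcript	consequence	cdna_change	protein_change	gnomad_af	kaviar_af	pli	mis_z	local_tolerance	sift	polyphen	revel	gerp	brain_expressed	in_segdup	dist_to_transcript_end	affects_protein_domain	splice_site_class	classification
01	1	53742664	G	A	LRP8	NM_001018054	missense	c.G583A	p.G195S	2.5e-05	0	1.00	2.77	highly_intolerant	D	P	0.669	2.91	1	0	.	0	not_splice	VUS
02	1	10318654	A	G	KIF1B	NM_015074	missense	c.A287G	p.Y96C	4.0e-06	0	1.0	3.6	intolerant	D	D	0.95	5.7	1	0	.	0	not_splice	VUS
03	4	140282956	G	T	NAA15	NM_057175	missense	c.G1618T	p.D540Y	8.0e-06	0	1.0	3.8	intolerant	D	D	0.54	6.0	1	0	.	0	not_splice	VUS
04	2	54845255	G	A	SPTBN1	NM_003128	missense	c.G688A	p.A230T	0	0	1.0	4.5	intolerant	D	D	0.86	5.6	1	0	.	0	not_splice	Likely pathogenic
04	6	165863831	A	C	PDE10A	NM_001130690	missense	c.A245C	p.Q82P	0	0	1.0	3.8	intolerant	D	D	0.53	4.6	1	0	.	0	not_splice	VUS
05	7	103124179	G	A	RELN	NM_005045	missense	c.G10102A	p.G3368R	5.7e-05	0	1.00	1.14	intolerant	D	D	0.703	5.72	1	0	.	0	not_splice	VUS/likely benign
05	10	27405184	G	A	YME1L1	NM_001253866	missense	c.G1711A	p.E571K	0	0	0.99	2.06	intolerant	D	D	0.943	5.43	1	0	.	0	not_splice	VUS
05	12	49333815	G	C	ARF3	NM_001659	missense	c.G224C	p.R75P	0	0	0.62	3.01	highly_intolerant	D	D	0.881	3.83	1	0	.	0	not_splice	Likely pathogenic
05	14	35240770	C	T	BAZ1A	NM_182648	missense	c.C3152T	p.A1051V	4.0e-06	0	1.00	2.69	intolerant	T	D	0.636	5.66	1	0	.	0	not_splice	VUS
06	19	42777266	G	T	CIC	NM_001304815	missense	c.G1331T	p.C444F	0	0	1.00	1.53	.	.	.	.	4.7	1	0	.	0	not_splice	VUS
07	9	140069703	G	A	ANAPC2	NM_013366	missense	c.G2242A	p.E748K	4.0e-06	0	1.00	2.43	intolerant	D	D	0.506	4.32	1	0	.	0	not_splice	VUS
07	19	41183304	T	C	NUMBL	NM_001289979	missense	c.T440C	p.V147A	0	0	1.00	3.18	intolerant	D	D	0.596	5.31	1	0	.	0	not_splice	VUS
08	5	45695972	A	AGCGGCGGCG	HCN1	NM_021072	inframe_indel	c.223_224insGCGGCGGCG	p.G74_E75insGGG	7.2e-05	0	1.0	3.72	intolerant	.	.	.	.	1	0	.	0	not_splice	Likely benign
08	12	122626291	C	G	MLXIP	NM_014938	missense	c.C2692G	p.P898A	0	0	0.98	1.87	intolerant	D	D	0.72	5.5	1	0	.	0	not_splice	VUS
09	9	130422360	C	T	STXBP1	NM_001032221	missense	c.C298T	p.R100W	7.1e-06	0	1.0	4.3	intolerant	D	D	0.70	4.6	1	0	.	0	not_splice	Likely pathogenic/VUS
09	10	75557014	AAAG	A	ZSWIM8	NM_001242487	inframe_indel	c.3403_3405del	p.K1137del	1.8e-05	0	1.00	5.53	intolerant	.	.	.	.	1	0	.	0	not_splice	VUS
10	11	120312519	C	A	ARHGEF12	NM_001198665	missense	c.C1139A	p.A380E	0	0	1.0	3.3	highly_intolerant	D	D	0.82	5.5	1	0	.	0	not_splice	VUS
10	20	50307357	A	G	ATP9A	NM_006045	missense	c.A644G	p.D215G	2.1e-05	0	1.0	4.2	intolerant	D	D	0.79	5.3	1	0	.	0	not_splice	VUS
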