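proband	chrom	pos	ref	alt	gene	transcript	consequence	cdna_change	protein_change	gnomad_af	kaviar_af	pli	mis_z	local_tolerance	sift	polyphen	revel	gerp	brain_expressed	in_segdup	dist_to_transcript_end	affects_protein_domain	splice_site_class	classification
14	4	55979624	C	T	KDR	NM_002253	stop_gain	c.C823T	p.R275X	0	0	1.00	.	.	.	.	.	5.5	1	0	3243	0	not_splice	VUS
15	2	101620700	G	A	RPL31	NM_000993	missense	c.G188A	p.R63H	4.0e-06	0	.	1.6	intolerant	T	T	0.77	4.2	1	0	.	0	not_splice	VUS
16	3	52556182	A	G	STAB1	NM_015136	missense	c.A6401G	p.N2134S	0	0	.	1.1	slightly_tolerant	D	P	0.44	5.6	1	0	.	0	not_splice	VUS
17	11	18723515	C	T	TMEM86A	NM_153347	missense	c.C682T	p.R228W	2.0e-05	0	.	0.9	slightly_tolerant	D	D	0.17	5.6	1	0	.	0	not_splice	VUS
18	16	77325369	G	C	ADAMTS18	NM_199355	missense	c.G3196C	p.A1066P	0	0	.	-3.5	slightly_intolerant	D	P	0.23	1.5	1	0	.	0	not_splice	VUS
19	19	17631811	C	A	PGLS	NM_012088	missense	c.C698A	p.T233N	0	0	.	0.2	intolerant	T	T	0.09	5.3	1	0	.	0	not_splice	VUS
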