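proband	chrom	pos	ref	alt	gene	transcript	consequence	cdna_change	protein_change	gnomad_af	kaviar_af	pli	mis_z	local_tolerance	sift	polyphen	revel	gerp	brain_expressed	in_segdup	dist_to_transcript_end	affects_protein_domain	splice_site_class	classification
01	16	30991037	ACCCTGCGCCAG	A	SETD1A	NM_014712	frameshift	c.3930_3940delCCCTGCGCCAG	p.P1313Afs*17	0	0	1.00	.	.	.	.	.	.	1	0	1182	1	not_splice	Pathogenic
02	2	242122172	AC	A	PPP1R7	NM_002712	frameshift	c.1017delC	p.R340Gfs*111	0	0	0.99	.	.	.	.	.	.	1	0	60	0	not_splice	VUS
04	5	145859585	ATAGTTA	A	TCERG1	NM_006706	splice	c.1820-3_1822delTAGTTA	?	2.2e-05	0	1.00	.	.	.	.	.	.	1	0	.	0	main_donor_acceptor	VUS
06	16	67580073	C	G	RIPOR1	NM_024519	stop_gain	c.C3501G	p.Y1167X	0	0	0.95	.	.	.	.	.	.	1	0	141	0	not_splice	VUS
06	17	38572722	AG	A	TOP2A	NM_001067	frameshift	c.220delG	p.E74Kfs*16	0	0	0.99	.	.	.	.	.	.	1	0	4371	0	not_splice	VUS
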