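proband	gene	inheritance	clinvar	protein_position
01	SETD1A	inherited_affected_parent	absent	1313
02	PPP1R7	inherited_unaffected_parent	absent	340
04	TCERG1	unknown	absent	.
06	RIPOR1	unknown	absent	1167
06	TOP2A	unknown	absent	74
01	LRP8	unknown	absent	195
02	KIF1B	unknown	absent	96
03	NAA15	inherited_unaffected_parent	absent	540
04	SPTBN1	unknown	absent	230
04	PDE10A	unknown	absent	82
05	RELN	unknown	likely_benign	3368
05	YME1L1	unknown	absent	571
05	ARF3	unknown	absent	75
05	BAZ1A	unknown	absent	1051
06	CIC	unknown	absent	444
07	ANAPC2	unknown	absent	748
07	NUMBL	unknown	absent	147
08	HCN1	unknown	likely_benign	74
08	MLXIP	unknown	absent	898
09	STXBP1	unknown	conflicting	100
09	ZSWIM8	unknown	absent	1137
10	ARHGEF12	unknown	absent	380
10	ATP9A	unknown	absent	215
14	KDR	de_novo	absent	275
15	RPL31	de_novo	absent	63
16	STAB1	de_novo	absent	2134
17	TMEM86A	de_novo	absent	228
18	ADAMTS18	de_novo	absent	1066
19	PGLS	de_novo	absent	233
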