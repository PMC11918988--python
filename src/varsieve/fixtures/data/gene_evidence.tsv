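gene	established_ndd_gene	lof_mechanism	missense_mechanism	causal_cluster	domain_critical	phenotype_similarity	notes
SETD1A	1	1	0	.	0	overlapping	haploinsufficiency disorder incl. delayed speech/language; reported in childhood apraxia of speech
PPP1R7	0	0	0	.	0	unknown	single de novo pLoF in an autism cohort; no enrichment evidence
TCERG1	0	0	0	.	0	unknown	no prior disorder association
RIPOR1	0	0	0	.	0	unknown	no prior disorder association
TOP2A	0	0	0	.	0	unknown	no prior disorder association
LRP8	0	0	0	.	0	unknown	no prior disorder association
KIF1B	1	0	1	.	0	dissimilar	Charcot-Marie-Tooth type 2A1: peripheral neuropathy, dissimilar to speech delay
NAA15	1	1	1	450-484	0	overlapping	NDD with variable ID and delayed speech; causal missense cluster aa 450-484
SPTBN1	1	0	1	173-276	0	overlapping	NDD with ID/language delay; causal missense cluster in second calponin homology domain
PDE10A	0	0	0	.	0	dissimilar	striatal degeneration phenotype
RELN	1	0	1	.	0	overlapping	autism/epilepsy/lissencephaly associations
YME1L1	0	0	0	.	0	unknown	no prior disorder association
ARF3	1	0	1	70-80	0	overlapping	NDD with brain and skeletal abnormalities; switch-2 domain critical for GTP/GDP binding
BAZ1A	0	0	0	.	0	unknown	no prior disorder association
CIC	1	1	1	200-268	0	overlapping	ID/autism/ADHD; single causal missense within the HMG-box domain
ANAPC2	0	0	0	.	0	unknown	no prior disorder association
NUMBL	0	0	0	.	0	unknown	no prior disorder association
HCN1	1	0	1	.	0	overlapping	infantile epileptic encephalopathy
MLXIP	0	0	0	.	0	unknown	no prior disorder association
STXBP1	1	1	1	.	0	overlapping	neurodevelopmental delay and seizures; pathogenic hotspots elsewhere in the protein
ZSWIM8	0	0	0	.	0	unknown	no prior disorder association
ARHGEF12	0	0	0	.	0	unknown	no prior disorder association
ATP9A	0	0	0	.	0	unknown	no prior disorder association
KDR	0	0	0	.	0	unknown	pLoF reported in NDD/autism and pulmonary arterial hypertension; causal role unproven
RPL31	0	0	0	.	0	unknown	no prior disorder association
STAB1	0	0	0	.	0	unknown	no prior disorder association
TMEM86A	0	0	0	.	0	unknown	no prior disorder association
ADAMTS18	0	0	0	.	0	unknown	no prior disorder association
PGLS	0	0	0	.	0	unknown	no prior disorder association
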