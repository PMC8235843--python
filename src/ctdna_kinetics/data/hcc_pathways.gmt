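WNT_PATHWAY	curated subset: GO canonical WNT signaling; Reactome beta-catenin-independent WNT signaling	CTNNB1	APC	GNAS	RNF43
PI3K_MTOR_PATHWAY	curated subset: GO phosphatidylinositol 3-kinase signaling; Reactome MTOR signalling	PIK3CA	PTEN	MTOR	AKT1	STK11	TSC1
CELL_CYCLE_CONTROL	curated subset: GO cell cycle; Reactome cell cycle	TP53	RB1	ATM	CDKN2A	CCND1	CCNE1	CDK4	CDK6	MYC
CHROMATIN_REMODELING	curated subset: GO chromatin remodeling; Reactome chromatin modifying enzymes	ARID1A	SMARCA4	KMT2D
TELOMERE_MAINTENANCE	TERT promoter hotspot region	TERT
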