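# Local variant-drug knowledge base (no live queries). Rows transcribe the
# published evidence report for emergent variants under lenvatinib plus the
# source knowledge-base labels (OncoKB/CGI/CancerVar/CanDL vocabularies).
gene	scope	pattern	drug	effect	tier	source	reference	cancer_type
ARID1A	variant_class	oncogenic_mutation	ATR inhibitors	responsive	case_preclinical	CancerVar	PMID:27958275
ARID1A	variant_class	oncogenic_mutation	EZH2 inhibitor	responsive	case_preclinical	CancerVar	PMID:25686104
ARID1A	variant_class	oncogenic_mutation	PARP inhibitor	responsive	case_preclinical	CancerVar	PMID:26069190
CTNNB1	variant_class	oncogenic_mutation	Tankyrase inhibitor	resistant	case_preclinical	CancerVar	PMID:23539443
DDR2	variant_class	any_mutation	Dasatinib	responsive	case_preclinical	CancerVar	PMID:22328973	lung squamous cell carcinoma
ESR1	variant_class	oncogenic_mutation	Fulvestrant	responsive	late_trials	CGI|CancerVar	PMID:27269946	breast cancer
ESR1	variant_class	oncogenic_mutation	Exemestane	resistant	late_trials	CGI|CancerVar	PMID:27269946	breast cancer
ESR1	variant_class	oncogenic_mutation	AZD9496	responsive	LEVEL_3A	OncoKB	PMID:27986707|PMID:27269946|PMID:31563959	breast cancer
ESR1	variant_class	oncogenic_mutation	Fulvestrant	responsive	LEVEL_3A	OncoKB	PMID:27986707|PMID:27269946|PMID:31563959	breast cancer
TP53	exact_variant	G245S	AMG MDS3	resistant	case_preclinical	CancerVar	PMID:25730903
TP53	variant_class	oncogenic_mutation	Abemaciclib	resistant	Early trials	CGI|CancerVar	PMID:27217383
TP53	variant_class	oncogenic_mutation	Cisplatin	resistant	Early trials	CGI|CancerVar	PMID:27646943
TP53	variant_class	oncogenic_mutation	AZD6738	responsive	Early trials	CGI|CancerVar	NCT01955668
TP53	variant_class	oncogenic_mutation	Decitabine	responsive	Early trials	CGI|CancerVar	PMID:27959731
TP53	variant_class	oncogenic_mutation	Doxorubicin	responsive	case_preclinical	CancerVar	PMID:27397505
TP53	variant_class	oncogenic_mutation	Gemcitabine	responsive	case_preclinical	CancerVar	PMID:27397505
TP53	variant_class	oncogenic_mutation	Mitomycin C	responsive	case_preclinical	CancerVar	PMID:27397505
TP53	variant_class	oncogenic_mutation	WEE1 inhibitor	responsive	case_preclinical	CancerVar	PMID:25125259|PMID:27998224
TP53	variant_class	oncogenic_mutation	MDM2 inhibitor	resistant	case_preclinical	CancerVar	PMID:23084521
TP53	variant_class	oncogenic_mutation	Pramlintide	responsive	case_preclinical	CancerVar	PMID:25409149
AR	variant_class	any_mutation	Nilutamide	resistant	case_preclinical	CancerVar	PMID:26000489	prostate cancer
AR	variant_class	any_mutation	Cyproterone acetate	resistant	case_preclinical	CancerVar	PMID:26000489	prostate cancer
AR	variant_class	any_mutation	Flutamide	resistant	case_preclinical	CancerVar	PMID:26000489	prostate cancer
AR	variant_class	any_mutation	Bicalutamide	resistant	case_preclinical	CancerVar	PMID:26000489	prostate cancer
ATM	exact_variant	R2832H	Olaparib	responsive	LEVEL_1	OncoKB	PMID:32343890
ATM	variant_class	oncogenic_mutation	Cisplatin	responsive	Early trials	CGI|CancerVar	PMID:26238431
ATM	variant_class	oncogenic_mutation	Olaparib	responsive	Early trials	CGI|CancerVar	PMID:26510020
ATM	variant_class	oncogenic_mutation	ATR inhibitor	responsive	case_preclinical	CancerVar	ENA 2015 (abstr A48)
ATM	variant_class	oncogenic_mutation	Temozolomide	responsive	case_preclinical	CancerVar	PMID:23960094
ATM	variant_class	oncogenic_mutation	DNA-PKc inhibitor	responsive	case_preclinical	CancerVar	PMID:23761041
ATM	variant_class	oncogenic_mutation	PARP inhibitor	responsive	case_preclinical	CancerVar	ENA 2014 (abstr 8LBA)
ATM	variant_class	oncogenic_mutation	Olaparib	responsive	LEVEL_4	OncoKB	PMID:20739657|PMID:26510020
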