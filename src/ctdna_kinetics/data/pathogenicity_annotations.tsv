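# Local pathogenicity annotation table (stands in for OncoKB / ClinVar /
# COSMIC / CancerVar lookups; no live queries). scope: exact_variant |
# variant_class | gene_level. Class patterns use the consequence vocabulary
# (oncogenic_mutation, frameshift, nonsense, missense, promoter, splice_site,
# any_mutation).
gene	scope	pattern	verdict	source
ATM	exact_variant	R2832H	pathogenic	OncoKB
ATM	variant_class	missense	likely_pathogenic	CancerVar
ATM	variant_class	frameshift	likely_pathogenic	CancerVar
ARID1A	variant_class	frameshift	likely_pathogenic	CancerVar
ARID1A	variant_class	nonsense	likely_pathogenic	CancerVar
CTNNB1	variant_class	missense	likely_pathogenic	CancerVar
DDR2	variant_class	missense	likely_pathogenic	CancerVar
ESR1	variant_class	nonsense	likely_pathogenic	CGI|CancerVar
ESR1	variant_class	missense	likely_pathogenic	CGI|CancerVar
TP53	variant_class	any_mutation	pathogenic	CancerVar
AR	variant_class	missense	likely_pathogenic	CancerVar
NFE2L2	variant_class	missense	likely_pathogenic	CancerVar
TERT	variant_class	promoter	likely_pathogenic	CancerVar
RB1	variant_class	nonsense	likely_pathogenic	ClinVar
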