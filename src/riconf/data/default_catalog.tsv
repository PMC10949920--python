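code	name	category	group	base_level	aspect	assay_context
EXP-IDA-BINDING-OF-PURIFIED-PROTEINS	Binding of purified protein (EMSA, footprinting)	classical	1	strong	binding	in_vitro
EXP-SITE-MUTATION	Site mutation	classical	2	strong	binding	in_vivo
EXP-IDA-BINDING-OF-CELLULAR-EXTRACTS	Binding of cellular extracts	classical	3	weak	binding	in_vitro
HT-EXP-IDA-CHIP-CHIP	ChIP-chip	ht	4	weak	binding	in_vivo
HT-EXP-IDA-CHIP-SEQ	ChIP-seq	ht	4	weak	binding	in_vivo
HT-EXP-IDA-CHIP-EXO	ChIP-exo	ht	4	weak	binding	in_vivo
HT-EXP-IDA-GSELEX	Genomic SELEX screening	ht	5	weak	binding	in_vitro
HT-EXP-IDA-DAP-SEQ	DNA affinity purification sequencing	ht	6	weak	binding	in_vitro
COMP-ANALYSIS	Computational analysis	nonexperimental	7	weak	binding	na
EXP-GENE-EXPRESSION-ANALYSIS	Gene expression analysis	classical		weak	function	in_vivo
HT-EXP-GENE-EXPRESSION-ANALYSIS	HT gene expression analysis (RNA-seq)	ht		weak	function	in_vivo
AS-AUTHOR-STATEMENT	Author statement	nonexperimental		weak	binding	na
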