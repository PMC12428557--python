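ase_class	gene_id	gene_symbol	delta_psi	fdr
A3SS	ENSG00000126215	XRCC3	0.357	0.0043
A3SS	ENSG00000221829	FANCG	-0.169	0.0350
A3SS	ENSG00000187741	FANCA	-0.173	0.0382
A3SS	ENSG00000177084	POLE	0.152	0.0330
A5SS	ENSG00000221829	FANCG	-0.301	0.0070
MXE	ENSG00000012048	BRCA1	0.111	0.0468
RI	ENSG00000136492	BRIP1	-0.291	0.0084
RI	ENSG00000100749	VRK1	0.107	0.0451
RI	ENSG00000221829	FANCG	-0.326	0.0028
RI	ENSG00000141510	TP53	-0.378	0.0037
RI	ENSG00000187741	FANCA	-0.194	0.0123
SE	ENSG00000183765	CHEK2	0.293	0.0316
SE	ENSG00000138376	BARD1	0.254	0.0140
SE	ENSG00000221829	FANCG	-0.162	0.0356
SE	ENSG00000111752	PHC1	-0.284	0.0399
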