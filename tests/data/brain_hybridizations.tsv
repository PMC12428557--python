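ase_class	gene_symbol	mirna	delta_psi	mfe
A3SS	XRCC3	hsa-miR-210-3p	0.357	-33.8
A3SS	FANCG	hsa-miR-423-5p	-0.169	-30.3
A5SS	FANCG	hsa-miR-423-5p	-0.301	-30.3
MXE	BRCA1	hsa-miR-1301-3p	0.111	-30.4
RI	BRIP1	hsa-miR-127-3p	-0.291	-31.5
RI	BRIP1	hsa-miR-766-3p	-0.291	-30.4
RI	FANCG	hsa-miR-423-5p	-0.326	-30.3
SE	CHEK2	hsa-miR-874-3p	0.293	-30.6
SE	CHEK2	hsa-miR-877-5p	0.293	-36.9
SE	CHEK2	hsa-miR-887-3p	0.293	-35
SE	FANCG	hsa-miR-423-5p	-0.162	-30.3
SE	FANCG	hsa-miR-671-5p	-0.162	-30.7
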