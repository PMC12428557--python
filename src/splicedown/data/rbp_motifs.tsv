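# Illustrative RBP recognition motifs (IUPAC, RNA alphabet). The authoritative
# motif list used by motif-map servers is user-suppliable via --motifs; this
# default set covers the splicing-factor families exercised by the pipeline.
RBFOX1	UGCAUG
SRSF1	RGAAGAAC
SRSF2	SSNGGA
SRSF3	WCWWC
SRSF6	URGAGU
SRSF7	ACGAGAGAY
SRSF9	AGGACM
FXR1	WGGA,GACR
FXR2	GACARG
FMR1	GACR
HNRNPK	CCCWCCC
PABPC4	AAAAAA
ANKHD1	AUUUA
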