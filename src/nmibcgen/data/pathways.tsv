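pathway	genes
RTK-RAS	FGFR3;HRAS;KRAS;NRAS;ERBB2;ERBB3;EGFR;BRAF;NF1;RAF1;PDGFRA;MET
PI3K	PIK3CA;PTEN;AKT1;TSC1;TSC2;MTOR;RICTOR;PIK3R1
TP53	TP53;MDM2;MDM4;ATM;CHEK2;RPS6KA3
Cell-Cycle	CDKN2A;CDKN1A;CDKN2B;RB1;CCND1;CCNE1;CDK4;CDK6;E2F3
Hippo	LATS1;LATS2;NF2;FAT1;YAP1;TAOK1
Myc	MYC;MYCL;MYCN;MAX;MGA;MNT
Notch	NOTCH1;NOTCH2;NOTCH3;FBXW7;CREBBP;EP300;SPEN
Wnt	APC;CTNNB1;TCF7L2;AXIN1;AXIN2;RNF43
TGF-Beta	TGFBR1;TGFBR2;SMAD2;SMAD3;SMAD4;ACVR2A
Nrf2	NFE2L2;KEAP1;CUL3
Histone-Modification	EP300;CREBBP;KMT2C;KMT2D;KDM6A;BAP1;ASXL1;ASXL2;SETD2
SWI-SNF	ARID1A;ARID1B;ARID2
DNA-Damage	ERCC2;BRIP1;ATM;BRCA1;BRCA2;RAD21;RAD50;CHEK1
Cohesin	STAG1;STAG2;RAD21;SMC1A;SMC3
Oxidative-Stress	NFE2L2;KEAP1;CUL3;TXNIP
Alternative-Splicing	RBM10;SF3B1;U2AF1;CDK12
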