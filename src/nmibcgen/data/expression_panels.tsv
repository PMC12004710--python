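panel	genes
basal	KRT5;KRT6A;KRT14;CD44;CDH3
luminal	KRT20;PPARG;FOXA1;GATA3;SNX31;UPK1A;UPK2;FGFR3
p53	TP53;ACTG2;CNN1;MYH11;MFAP4;PGM5;FLNC;ACTC1;DES;PCP4
stroma	PDGFRB;FAP;COL1A1;COL1A2;COL5A1;COL6A3;POSTN;VIM
inflammation	IL6;IL1B;CXCL8;CCL2;TNF;PTGS2;NFKB1;STAT3
claudin_low	CLDN3;CLDN4;CLDN7;CDH1;VIM;ZEB1;ZEB2;TWIST1;SNAI2
immune_checkpoint	CD274;PDCD1;CTLA4;LAG3;HAVCR2;TIGIT;IDO1
interferon	STAT1;IRF1;GBP1;CXCL9;CXCL10;IFIT1;IFIT3;ISG15;MX1
bcg_response	HLA-DRA;HLA-DRB1;CD74;CIITA;CXCL9;CXCL10;GZMB;PRF1
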