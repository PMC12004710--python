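gene	mutant_european	total_european	mutant_chinese	total_chinese
ARID1A	25	127	8	58
CREBBP	20	127	14	58
EP300	23	127	9	58
FGFR3	83	127	32	58
KDM6A	59	127	18	58
KMT2D	34	127	24	58
PIK3CA	54	127	11	58
RBM10	13	127	3	58
STAG2	41	127	11	58
TP53	3	127	7	58
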