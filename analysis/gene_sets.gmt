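UPR_ATF6_branch	synthetic illustrative set over simulated gene names	HSP90B1	CALR	SDF2L1	HYOU1
UPR_IRE1_branch	synthetic illustrative set over simulated gene names	XBP1	PDIA5	PDIA6	DNAJB11	DNAJB9	DNAJC3
ER_chaperones	synthetic illustrative set over simulated gene names	HSPA5	HSP90B1	CALR	CANX	HYOU1
ERAD	synthetic illustrative set over simulated gene names	EDEM1	SEC61B	SSR4	SDF2L1
protein_folding_noise	synthetic illustrative set over simulated gene names	CANX	ERP29	ERP44	MANF	P4HB
unrelated_control	synthetic illustrative set over simulated gene names	G00010	G00020	G00030	G00040	G00050	G00060
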