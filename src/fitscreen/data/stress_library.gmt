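general_stress	General stress response	TPS1	TPS2	TSL1	NTH1	HOG1	GPD1	SLN1	MSB2	GSY2	HXK1	GLK1	PFK26	FBP26	PGM2	TPK1	TPK2	CDC28	YAP1	CDC48	CDC6	MCA1	NMA111	TATD	FIS1	OYE2	YSP2	COX17	COR1	CYC7	GND2
oxidative_stress	Oxidative stress	YAP1	SLN1	SKN7	MSN2	SOD1	CTT1	GRX1	GRX2	GSH1	GPX1	GTT1	HYR1	ECM38	TRX2	TSA2	ISM1	ATM1	CCP1	PRX1
chemical_stress	Chemical stress	PUN1	HSP12	MSN2	PDR1	PDR3	YCF1	PDR5	SNQ2	BPT1	ATM1	FLR1	QDR2	ATR1	TPO1	AQR1	QDR3	TOP2	YRR1	YRM1	BSD2	ATF2	YHB1	ECM38
protein_stress	Protein stress	HSP104	HSP42	HSP78	HSP26	SSA4	SSA3	SSE2	TIR1	TIP1	BFR2	IRE1	HAC1	UBC5	UBC8	ATG1	UTH1
dna_stress	DNA stress	CHK1	MMS2	PHR1	OGG1	NTG1	NTG2	UNG1	MAG1	RAD27	APN1	APN2	RAD1	RAD2	RAD4	RAD9	RAD14	RAD16	RAD23	RAD30	RAD34	MSH1	MSH2	MSH3	MSH6	PMS1	MLH1	MLH2	XRS2	MRE11	RFA1	RFA2	RFA3	RAD51	RAD52	RAD54	HTA1	HTA2	LIF1	YKU70
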