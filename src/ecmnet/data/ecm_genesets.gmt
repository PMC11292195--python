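PROTEOGLYCANS	11-protein proteoglycan signature (SLRP classes I-III, hyalectans, basement-membrane zone); final member transcribed with uncertainty	ACAN	VCAN	HSPG2	BGN	DCN	ASPN	FMOD	LUM	PRELP	OGN	HAPLN1
BASEMENT_MEMBRANE	Basement membrane components	COL4A1	COL4A2	LAMA4	LAMA5	LAMB2	LAMC1	NID1	NID2	HSPG2	COL15A1
COLLAGENS	Collagen chains	COL1A1	COL1A2	COL2A1	COL3A1	COL4A1	COL4A2	COL5A1	COL5A2	COL6A1	COL6A2	COL6A3	COL15A1
CORE_MATRISOME	Core matrisome: collagens, glycoproteins and proteoglycans	COL1A1	COL1A2	COL3A1	COL4A1	COL4A2	COL5A1	COL6A1	FN1	LAMA4	LAMB2	LAMC1	NID1	NID2	ACAN	VCAN	HSPG2	BGN	DCN	LUM	OGN
ECM_REGULATORS	ECM remodeling enzymes and their regulators	CTSB	CTSS	CTSZ	CTSA	MMP14	PLOD1	PLOD2	LOX	P4HA1	PLAUR
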