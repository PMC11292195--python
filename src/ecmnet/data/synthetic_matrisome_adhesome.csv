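gene,division,category
COL1A1,core_matrisome,collagens
COL1A2,core_matrisome,collagens
COL2A1,core_matrisome,collagens
COL3A1,core_matrisome,collagens
COL4A1,core_matrisome,collagens
COL4A2,core_matrisome,collagens
COL5A1,core_matrisome,collagens
COL5A2,core_matrisome,collagens
COL6A1,core_matrisome,collagens
COL6A2,core_matrisome,collagens
COL6A3,core_matrisome,collagens
COL15A1,core_matrisome,collagens
FN1,core_matrisome,glycoproteins
LAMA4,core_matrisome,glycoproteins
LAMA5,core_matrisome,glycoproteins
LAMB2,core_matrisome,glycoproteins
LAMC1,core_matrisome,glycoproteins
NID1,core_matrisome,glycoproteins
NID2,core_matrisome,glycoproteins
MATN2,core_matrisome,glycoproteins
TINAGL1,core_matrisome,glycoproteins
VWA1,core_matrisome,glycoproteins
FBN1,core_matrisome,glycoproteins
FBLN2,core_matrisome,glycoproteins
MFAP2,core_matrisome,glycoproteins
MFAP5,core_matrisome,glycoproteins
ACAN,core_matrisome,proteoglycans
VCAN,core_matrisome,proteoglycans
HSPG2,core_matrisome,proteoglycans
BGN,core_matrisome,proteoglycans
DCN,core_matrisome,proteoglycans
ASPN,core_matrisome,proteoglycans
FMOD,core_matrisome,proteoglycans
LUM,core_matrisome,proteoglycans
PRELP,core_matrisome,proteoglycans
OGN,core_matrisome,proteoglycans
HAPLN1,core_matrisome,proteoglycans
CTSB,matrisome_associated,ECM_regulators
CTSS,matrisome_associated,ECM_regulators
CTSZ,matrisome_associated,ECM_regulators
CTSA,matrisome_associated,ECM_regulators
MMP14,matrisome_associated,ECM_regulators
PLOD1,matrisome_associated,ECM_regulators
PLOD2,matrisome_associated,ECM_regulators
LOX,matrisome_associated,ECM_regulators
P4HA1,matrisome_associated,ECM_regulators
PLAUR,matrisome_associated,ECM_regulators
SERPINA1,matrisome_associated,ECM_regulators
SERPINC1,matrisome_associated,ECM_regulators
S100A4,matrisome_associated,secreted_factors
S100A8,matrisome_associated,secreted_factors
S100A9,matrisome_associated,secreted_factors
ANXA1,matrisome_associated,ECM_affiliated
ANXA2,matrisome_associated,ECM_affiliated
LGALS1,matrisome_associated,ECM_affiliated
LGALS3,matrisome_associated,ECM_affiliated
LCP1,adhesome,adaptor
TLN1,adhesome,adaptor
VCL,adhesome,adaptor
PXN,adhesome,adaptor
ZYX,adhesome,adaptor
FLNA,adhesome,adaptor
ACTN1,adhesome,adaptor
ITGA5,adhesome,adhesion_receptor
ITGB1,adhesome,adhesion_receptor
ITGB3,adhesome,adhesion_receptor
ITGAV,adhesome,adhesion_receptor
PTK2,adhesome,kinase
SRC,adhesome,kinase
ILK,adhesome,kinase
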