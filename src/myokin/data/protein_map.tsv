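reaction_id	protein_group
R_GLUT1	SLC2A1
R_GLUT4	SLC2A4
R_HK1	HK1
R_HK2	HK2
R_GLY	PFKM
R_GLY	GAPDH
R_GLY	PKM
R_LDH	LDHA
R_LDH	LDHB
R_MCT_LAC	SLC16A1
R_MCT_PYR	SLC16A3
R_MAS	GOT2
R_MAS	MDH1
R_MAS	SLC25A12
R_PDH	PDHA1
R_PDH	DLAT
R_PDH	DLD
R_FAT	CD36
R_ACS1	ACSL1
R_ACS2	ACSL3
R_CPT1	CPT1B
R_CACT	SLC25A20
R_CPT2	CPT2
R_BOX	ACADVL
R_BOX	HADHA
R_BOX	HADHB
R_MCT_KB	SLC16A7
R_KET	BDH1
R_KET	OXCT1
R_KET	ACAT1
R_BCAAT	SLC7A5
R_BCAAOX	BCAT2
R_BCAAOX	BCKDHA
R_BCAAOX	BCKDHB
R_TCA	CS
R_TCA	IDH3A
R_TCA	OGDH
R_TCA	MDH2
R_TCA	SUCLA2
R_C1	NDUFS1
R_C1	NDUFV1
R_C1	UQCRC1
R_C1	COX4I1
R_C2	SDHA
R_C2	ETFA
R_C2	ETFDH
R_SYN	ATP5F1A
R_SYN	ATP5F1B
R_ANT	SLC25A4
R_KHE	LETM1
R_AK	AK1
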