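SatelliteCell	Satellite cell signature (10 genes), human symbols	CHRDL2	CLCF1	CRLF1	DHCR24	ERFE	FOSL1	MYF5	NPPC	PAX7	PDE10A
MyoblastMyocyte	Myoblast/Myocyte signature (25 genes), human symbols	BEX1	CAPN6	CAV3	CHRNA1	FNDC5	GPC1	IFFO1	IQSEC3	LRRN1	MEGF10	MYH3	MYL4	MYMK	MYMX	MYOG	PNMA8B	POPDC3	RAPSN	RTN2	SCRIB	SYTL2	TNNC1	TNNI1	TNNT1	TNNT2
Myonuclear	Myonuclear (type I/IIa/IIx) signature (66 genes), human symbols	ABCB4	ACSS2	ADAMTSL5	AGBL1	AKAP1	AKAP6	ANKRD2	ANKRD52	ANO5	AOX1	APOL6	ASB10	ATP1B4	C10orf71	CLASP2	COQ8A	CRHR2	CSRP3	DMAC2	DNAJB5	DUSP18	FABP3	FEM1A	FSD2	GMPR	GPR157	HOMER2	HSPB7	ITGB6	IVD	KCNA7	KCNJ2	KCNN2	KCNQ4	LMOD2	LMOD3	LRPPRC	MAPK1IP1L	MYH2	MYOZ2	NOS1	PADI2	PDK4	PFKFB1	PPARGC1A	PPARGC1B	PPFIBP2	PRICKLE3	PTPN3	RILP	RMND1	RPS6KA2	SACS	SLC25A12	SLF1	SMTNL1	SORBS1	SYNJ2	SYNPO2L	TBX1	TMEM52	USP28	XIRP1	YIPF7	ZCCHC4	ZNF17
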