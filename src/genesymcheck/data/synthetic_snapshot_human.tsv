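#species	human
#build_date	2024-01-01
#source_label	synthetic demonstration fixture
key	approved	source_kind	chromosome
01-DEC	DEC1	mogrified	9
01-Dec	DEC1	mogrified	9
01-MAR	MARC1	mogrified	1
01-MAR	MARCH1	mogrified	4
01-Mar	MARC1	mogrified	1
01-Mar	MARCH1	mogrified	4
01-SEP	SEPT1	mogrified	16
01-Sep	SEPT1	mogrified	16
1-DEC	DEC1	mogrified	9
1-DECEMBER	DEC1	mogrified	9
1-Dec	DEC1	mogrified	9
1-December	DEC1	mogrified	9
1-MAR	MARC1	mogrified	1
1-MAR	MARCH1	mogrified	4
1-MARCH	MARC1	mogrified	1
1-MARCH	MARCH1	mogrified	4
1-Mar	MARC1	mogrified	1
1-Mar	MARCH1	mogrified	4
1-March	MARC1	mogrified	1
1-March	MARCH1	mogrified	4
1-SEP	SEPT1	mogrified	16
1-SEPTEMBER	SEPT1	mogrified	16
1-Sep	SEPT1	mogrified	16
1-September	SEPT1	mogrified	16
2.31001E+19	2310009E13	mogrified	7
2310009E13	2310009E13	approved_identity	7
AMPUJ5	AMPUJ5	approved_identity	2
ARR2	ARR2	approved_identity	X
BCVH23	ENH7	alias	
BDQV86	OQKP96	previous_symbol	7
BFL1	ZXC59	alias	2
C9orf72	C9orf72	approved_identity	9
CCEMO7	LNNS4	previous_symbol	
CCK6	NQVD39	alias	11
CDC7	PVHPT15	alias	X
CEGZ99	OCYOR9	previous_symbol	19
CFH	CFH	approved_identity	1
CLV3	CLV3	approved_identity	X
CVQZ4	ARR2	alias	X
DBG42	TVBT9	alias	
DEC-01	DEC1	mogrified	9
DEC1	DEC1	approved_identity	9
DIFF6	SEPT1	alias	16
DPDKJ1	OQKP96	alias	7
DPWI1	ZLB5	alias	X
DVAF59	DVAF59	approved_identity	19
Dec-01	DEC1	mogrified	9
EEP56	HMLP26	alias	X
ENH7	ENH7	approved_identity	
ESVLF7	OCYOR9	alias	19
EZGJ76	OQKP96	alias	7
FHL1	CFH	alias	1
FHL1	FHL1	approved_identity	X
GBGI6	TVBT9	previous_symbol	
GCN5L2	KAT2A	alias	17
GFGVN0	TVBT9	alias	
GRQR71	HMLP26	alias	X
HCU2	XOU5	alias	X
HF1	CFH	previous_symbol	1
HMLP26	HMLP26	approved_identity	X
HNQU83	RVZ00	alias	
HUGAN28	HMLP26	previous_symbol	X
HYZ2	OCYOR9	alias	19
IGJ4	PWLH98	alias	
IOP51	LKK68	alias	19
ISFW44	PVHPT15	previous_symbol	X
IZSFH8	QEPU1	alias	1
JBF30	ZAFR88	previous_symbol	19
JSXDL2	AMPUJ5	alias	2
JUMBR44	PWLH98	previous_symbol	
KAT2A	KAT2A	approved_identity	17
KEBP91	NQVD39	previous_symbol	11
KZSY7	NHJUH6	previous_symbol	1
LJS27	QEPU1	previous_symbol	1
LKK68	LKK68	approved_identity	19
LKNRM9	AMPUJ5	previous_symbol	2
LNNS4	LNNS4	approved_identity	
LUZI91	UJWJ0	previous_symbol	7
LWLRR64	RVZ00	previous_symbol	
MAR-01	MARC1	mogrified	1
MAR-01	MARCH1	mogrified	4
MARC1	MARC1	approved_identity	1
MARCH1	MARCH1	approved_identity	4
MFFO25	UJWJ0	alias	7
MGK51	DVAF59	previous_symbol	19
MLLMT91	ZXC59	previous_symbol	2
MRQ99	ZAFR88	alias	19
Mar-01	MARC1	mogrified	1
Mar-01	MARCH1	mogrified	4
NHJUH6	NHJUH6	approved_identity	1
NJXI63	AMPUJ5	alias	2
NQV11	ARR2	previous_symbol	X
NQVD39	NQVD39	approved_identity	11
OCYOR9	OCYOR9	approved_identity	19
OMJQG5	PVY4	previous_symbol	2
OQKP96	OQKP96	approved_identity	7
OTU10	XOU5	alias	X
OZJUE62	ZAFR88	alias	19
PCBAC84	YAJEV77	previous_symbol	5
PVHPT15	PVHPT15	approved_identity	X
PVLYW48	LNNS4	alias	
PVY4	PVY4	approved_identity	2
PWLH98	PWLH98	approved_identity	
QDADZ54	CLV3	previous_symbol	X
QEPU1	QEPU1	approved_identity	1
QHHRG4	CLV3	alias	X
QYN2	DVAF59	alias	19
RJZ18	LKK68	previous_symbol	19
ROUV5	QEPU1	alias	1
RVZ00	RVZ00	approved_identity	
SBAMX7	YAJEV77	alias	5
SBHW8	PVY4	alias	2
SEP-01	SEPT1	mogrified	16
SEPT1	SEPT1	approved_identity	16
SPMLS08	TPOK29	alias	11
SUQ17	ENH7	alias	
Sep-01	SEPT1	mogrified	16
TP53	TP53	approved_identity	17
TPOK29	TPOK29	approved_identity	11
TVBT9	TVBT9	approved_identity	
UCNZP28	NHJUH6	alias	1
UDA87	ZLB5	previous_symbol	X
UJWJ0	UJWJ0	approved_identity	7
ULVN9	DVAF59	alias	19
URMEN76	TPOK29	previous_symbol	11
UXYD3	PVY4	alias	2
VNF7	ZXC59	alias	2
VPOB7	ENH7	previous_symbol	
VQW9	UJWJ0	alias	7
VYRPU94	ARR2	alias	X
VZOPJ24	CLV3	alias	X
XAMSJ1	LKK68	alias	19
XDNFP48	XOU5	previous_symbol	X
XONV1	LNNS4	alias	
XOU5	XOU5	approved_identity	X
XVUA21	PVHPT15	alias	X
YAJEV77	YAJEV77	approved_identity	5
YCMU53	PWLH98	alias	
YKQP2	NQVD39	alias	11
YUAO6	ZLB5	alias	X
YUZRP79	TPOK29	alias	11
YVIQ19	YAJEV77	alias	5
ZAFR88	ZAFR88	approved_identity	19
ZFX8	RVZ00	alias	
ZLB5	ZLB5	approved_identity	X
ZVJQU24	NHJUH6	alias	1
ZXC59	ZXC59	approved_identity	2
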