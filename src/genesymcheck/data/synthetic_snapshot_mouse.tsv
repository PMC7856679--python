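#species	mouse
#build_date	2024-01-01
#source_label	synthetic demonstration fixture
key	approved	source_kind	chromosome
01-DEC	Bhlhe40	mogrified	6
01-Dec	Bhlhe40	mogrified	6
1-DEC	Bhlhe40	mogrified	6
1-DECEMBER	Bhlhe40	mogrified	6
1-Dec	Bhlhe40	mogrified	6
1-December	Bhlhe40	mogrified	6
2.31001E+19	2310009E13	mogrified	7
2310009E13	2310009E13	approved_identity	7
Absng1	Absng1	approved_identity	X
Azy6	Azy6	approved_identity	19
BOG17	Wockc04	alias	2
Bhlhe40	Bhlhe40	approved_identity	6
Brca-1	Brca1	alias	11
Brca1	Brca1	approved_identity	11
Bwqhu67	Bwqhu67	approved_identity	4
CJOL5	Kgul6	alias	11
CORE99	Bwqhu67	alias	4
CXF89	Ohivw19	alias	17
Cle2	Cle2	approved_identity	Y
Cvb5	Cvb5	approved_identity	Y
DEC-01	Bhlhe40	mogrified	6
DTHXS1	Wockc04	alias	2
Dec-01	Bhlhe40	mogrified	6
Dec-1 related	Bhlhe40	alias	6
Dec1	Bhlhe40	withdrawn_redirect	6
Dssj18	Dssj18	approved_identity	2
EHZY8	Vnys25	alias	1
ENIS34	Qip17	alias	7
Ftkx0	Ftkx0	approved_identity	
GCR2	Luc58	alias	19
GIR9	Ios63	alias	7
GJXL66	Mzhpk7	alias	2
GYUCS3	Cle2	alias	Y
HIOJ5	Mzhpk7	alias	2
HJZC16	Pqsvj45	alias	2
ICP08	Absng1	alias	X
ILXS00	Bwqhu67	alias	4
IXXVM2	Lxk5	alias	
Ios63	Ios63	approved_identity	7
Jblu98	Jblu98	approved_identity	1
KFV0	Jblu98	alias	1
KLOFM55	Pfdj1	alias	Y
Kgul6	Kgul6	approved_identity	11
Kuatg68	Kuatg68	approved_identity	X
LBQ8	Pzq79	alias	Y
LYF8	Pqsvj45	alias	2
Luc58	Luc58	approved_identity	19
Lxk5	Lxk5	approved_identity	
MAX05	Kuatg68	alias	X
MDM7	Vegoq46	alias	2
MHSCL76	Oul69	alias	11
MVFJT44	Dssj18	alias	2
MWES59	Cvb5	alias	Y
Mzhpk7	Mzhpk7	approved_identity	2
NTWP7	Lxk5	alias	
OBTOK36	Qth90	alias	11
Ohivw19	Ohivw19	approved_identity	17
Oul69	Oul69	approved_identity	11
PAF6	Qqs98	alias	
PNJYH6	Dssj18	alias	2
PWPG0	Ftkx0	alias	
Pfdj1	Pfdj1	approved_identity	Y
Pqsvj45	Pqsvj45	approved_identity	2
Pzq79	Pzq79	approved_identity	Y
QJI9	Kuatg68	alias	X
QZK18	Cle2	alias	Y
Qip17	Qip17	approved_identity	7
Qqs98	Qqs98	approved_identity	
Qth90	Qth90	approved_identity	11
SBG0	Qip17	alias	7
SCT75	Ftkx0	alias	
SHT1	Oul69	alias	11
STUE22	Jblu98	alias	1
SXERT01	Vegoq46	alias	2
TDA37	Qth90	alias	11
TKL62	Absng1	alias	X
TOKBP3	Pzq79	alias	Y
Trp53	Trp53	approved_identity	11
UTRS4	Ios63	alias	7
UXH5	Vnys25	alias	1
VAT6	Kgul6	alias	11
VXDOE6	Cvb5	alias	Y
Vegoq46	Vegoq46	approved_identity	2
Vnys25	Vnys25	approved_identity	1
WIOPP4	Luc58	alias	19
Wockc04	Wockc04	approved_identity	2
XDUI2	Qqs98	alias	
YJLF1	Azy6	alias	19
YYUNY00	Azy6	alias	19
ZRTIK41	Pfdj1	alias	Y
ZSVI91	Ohivw19	alias	17
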