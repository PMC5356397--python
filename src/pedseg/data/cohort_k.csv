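id,sire,dam,sex,diagnosed,age_years,alive,litter_id
OAN,,,male,0,11.0,0,
SPIG,,,female,0,13.0,0,
MYCK,,,female,0,9.5,0,
ART,,,male,0,10.0,0,
PEN,,,male,0,12.0,0,
KELL,,,female,0,9.5,0,
AMP,,,male,0,6.0,0,
SON,,,male,0,6.0,0,
RUF,,,male,0,10.0,0,
BELA,,,female,0,11.0,0,
DUNE,AMP,MYCK,female,1,7.5,0,K8
FERN,AMP,MYCK,female,1,8.0,0,K8
LANG,AMP,MYCK,female,0,12.0,0,K8
BEN,AMP,MYCK,male,0,10.0,0,K8
COL,AMP,MYCK,male,0,9.5,0,K8
GLEN,AMP,MYCK,male,0,9.0,0,K8
HAZE,AMP,MYCK,female,0,10.5,0,K8
IONA,AMP,MYCK,female,0,11.0,0,K8
KU27,AMP,MYCK,male,0,4.0,1,K8
KU28,AMP,MYCK,female,0,3.5,1,K8
EDIE,SON,KELL,female,1,7.0,0,K11
MORA,SON,KELL,female,1,8.5,0,K11
LIUM,SON,KELL,female,1,10.0,0,K11
NED,SON,KELL,male,1,6.5,0,K11
ROY,SON,KELL,male,1,7.5,0,K11
CRY,SON,KELL,male,0,11.0,0,K11
TAL,SON,KELL,male,0,10.0,0,K11
VALE,SON,KELL,female,0,9.0,0,K11
WREN,SON,KELL,female,0,9.5,0,K11
KU29,SON,KELL,male,0,5.0,1,K11
KU30,SON,KELL,female,0,4.5,1,K11
NORA,RUF,BELA,female,0,9.0,0,K12
KU35,RUF,BELA,male,0,3.0,1,K12
ISLA,TAL,LANG,female,1,6.0,0,K1
JURA,TAL,LANG,female,1,7.5,0,K1
KIP,TAL,LANG,male,0,10.0,0,K1
OBI,TAL,LANG,male,0,9.0,0,K1
MIRA,TAL,LANG,female,0,11.0,0,K1
NELL,TAL,LANG,female,0,8.5,1,K1
KU25,TAL,LANG,male,0,2.5,1,K1
KU26,TAL,LANG,female,0,2.0,1,K1
PIP,BEN,ISLA,male,1,7.0,0,K2
RHEA,COL,JURA,female,1,6.0,0,K3
SID,COL,JURA,male,1,8.0,0,K3
TESS,COL,JURA,female,0,9.5,0,K3
URSA,OAN,DUNE,female,1,5.5,0,K4
VIC,OAN,DUNE,male,1,7.0,0,K4
WES,OAN,DUNE,male,0,9.5,0,K4
XENA,OAN,DUNE,female,0,10.0,0,K4
KU31,OAN,DUNE,male,0,6.0,1,K4
YARA,WES,FERN,female,0,9.0,0,K5
ZED,CRY,EDIE,male,1,8.0,0,K6
ALBA,CRY,EDIE,female,0,9.0,0,K6
BRAE,CRY,EDIE,female,0,10.0,0,K6
CAM,CRY,EDIE,male,0,9.5,0,K6
KU32,CRY,EDIE,female,0,5.5,1,K6
DOON,CRY,SPIG,female,0,9.0,0,K7
FIN,ART,MORA,male,1,6.5,0,K9
GAIA,ART,MORA,female,1,7.5,0,K9
HAL,ART,MORA,male,0,9.0,0,K9
INES,ART,MORA,female,0,10.0,0,K9
JAY,ART,MORA,male,0,9.5,0,K9
KU33,ART,MORA,male,0,4.0,1,K9
KATE,PEN,LIUM,female,0,9.0,0,K10
LUNA,PEN,LIUM,female,0,10.0,0,K10
MAX,PEN,LIUM,male,0,9.5,0,K10
KU34,PEN,LIUM,female,0,6.5,1,K10
KU01,CAM,TESS,male,0,4.0,1,K13
KU02,CAM,TESS,female,0,4.0,1,K13
KU03,CAM,TESS,male,0,4.0,1,K13
KU04,CAM,TESS,female,0,4.0,1,K13
KU05,CAM,TESS,male,0,4.0,1,K13
KU06,CAM,TESS,female,0,4.0,1,K13
KU07,CAM,TESS,male,0,4.0,1,K13
KU08,CAM,TESS,female,0,4.0,1,K13
KU09,MAX,KATE,male,0,3.0,1,K14
KU10,MAX,KATE,female,0,3.0,1,K14
KU11,MAX,KATE,male,0,3.0,1,K14
KU12,MAX,KATE,female,0,3.0,1,K14
KU13,MAX,KATE,male,0,3.0,1,K14
KU14,MAX,KATE,female,0,3.0,1,K14
KU15,MAX,KATE,male,0,3.0,1,K14
KU16,MAX,KATE,female,0,3.0,1,K14
KU17,JAY,NORA,male,0,2.0,1,K15
KU18,JAY,NORA,female,0,2.0,1,K15
KU19,JAY,NORA,male,0,2.0,1,K15
KU20,JAY,NORA,female,0,2.0,1,K15
KU21,JAY,NORA,male,0,2.0,1,K15
KU22,JAY,NORA,female,0,2.0,1,K15
KU23,JAY,NORA,male,0,2.0,1,K15
KU24,JAY,NORA,female,0,2.0,1,K15
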