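id,sire,dam,sex,diagnosed,age_years,alive,litter_id
ABE,,,male,0,10.0,0,
LAVE,,,female,0,11.0,0,
VIK,,,male,0,10.5,0,
DENA,,,female,0,12.0,0,
COCA,,,female,0,9.5,0,
OTT,,,male,0,10.0,0,
PERL,,,female,0,11.0,0,
MIST,,,female,0,5.0,0,
RUNA,ABE,LAVE,female,1,7.0,0,T1
SAM,ABE,LAVE,male,0,9.5,0,T1
URI,ABE,LAVE,male,0,10.0,0,T1
VIDA,ABE,LAVE,female,0,9.0,0,T1
TU33,ABE,LAVE,male,0,3.0,1,T1
TU34,ABE,LAVE,female,0,3.0,1,T1
WYNN,VIK,DENA,female,1,8.0,0,T2
XARA,VIK,DENA,female,1,7.5,0,T2
YAN,VIK,DENA,male,0,9.0,0,T2
ZORA,VIK,DENA,female,0,10.0,0,T2
ASH,VIK,DENA,male,0,9.5,0,T2
TU35,VIK,DENA,male,0,4.0,1,T2
TU36,VIK,DENA,female,0,4.0,1,T2
BRYN,ABE,COCA,female,1,7.0,0,T8
CLIO,ABE,COCA,female,1,8.0,0,T8
DORA,ABE,COCA,female,0,9.0,0,T8
ELI,ABE,COCA,male,0,10.0,0,T8
FAWN,ABE,COCA,female,0,9.5,0,T8
GUS,ABE,COCA,male,0,9.0,0,T8
HOPE,ABE,COCA,female,0,10.5,0,T8
TU47,ABE,COCA,male,0,2.5,1,T8
IKE,OTT,PERL,male,0,10.0,0,T5
JET,OTT,PERL,male,0,9.5,0,T5
KODA,OTT,PERL,female,0,9.0,0,T5
LILA,OTT,PERL,female,0,10.0,0,T5
MAC,OTT,PERL,male,0,9.0,0,T5
NOVA,OTT,PERL,female,0,9.5,0,T5
TU41,OTT,PERL,male,0,5.0,1,T5
TU42,OTT,PERL,female,0,5.0,1,T5
OPAL,IKE,WYNN,female,1,6.0,0,T3
PAX,IKE,WYNN,male,1,7.0,0,T3
QUIN,IKE,WYNN,female,1,7.5,0,T3
REX,IKE,WYNN,male,1,8.0,0,T3
SUKI,IKE,WYNN,female,1,6.5,0,T3
TAZ,IKE,WYNN,male,1,9.0,0,T3
ULLA,IKE,WYNN,female,1,8.5,0,T3
RIF,IKE,WYNN,male,0,10.0,0,T3
VERA,IKE,WYNN,female,0,9.0,0,T3
TU37,IKE,WYNN,male,0,4.5,1,T3
TU38,IKE,WYNN,female,0,4.5,1,T3
WIL,SAM,XARA,male,1,7.0,0,T6
YSLA,SAM,XARA,female,1,6.5,0,T6
ZAC,SAM,XARA,male,1,8.0,0,T6
ADDA,SAM,XARA,female,1,7.5,0,T6
BIX,SAM,XARA,male,1,6.0,0,T6
CORA,SAM,XARA,female,1,9.0,0,T6
DAN,SAM,XARA,male,1,8.5,0,T6
EDDA,SAM,XARA,female,0,9.5,0,T6
FYN,SAM,XARA,male,0,9.0,0,T6
GILA,SAM,XARA,female,0,10.0,0,T6
TU43,SAM,XARA,male,0,3.5,1,T6
TU44,SAM,XARA,female,0,3.5,1,T6
HUX,JET,BRYN,male,1,6.5,0,T7
IRIS,JET,BRYN,female,1,7.0,0,T7
JON,JET,BRYN,male,1,8.0,0,T7
KIRA,JET,BRYN,female,1,7.5,0,T7
TU45,JET,BRYN,male,0,2.0,1,T7
TU46,JET,BRYN,female,0,2.0,1,T7
LEX,RIF,MIST,male,1,6.5,0,T4
MONA,RIF,MIST,female,0,9.0,0,T4
PIM,RIF,MIST,male,0,9.5,0,T4
SAGE,RIF,MIST,female,0,10.0,0,T4
TU39,RIF,MIST,male,0,4.0,1,T4
TU40,RIF,MIST,female,0,4.0,1,T4
TU01,RIF,KODA,male,0,3.0,1,T9
TU02,RIF,KODA,female,0,3.0,1,T9
TU03,RIF,KODA,male,0,3.0,1,T9
TU04,RIF,KODA,female,0,3.0,1,T9
TU05,RIF,KODA,male,0,3.0,1,T9
TU06,RIF,KODA,female,0,3.0,1,T9
TU07,RIF,KODA,male,0,3.0,1,T9
TU08,RIF,KODA,female,0,3.0,1,T9
TU09,MAC,NOVA,male,0,4.0,1,T10
TU10,MAC,NOVA,female,0,4.0,1,T10
TU11,MAC,NOVA,male,0,4.0,1,T10
TU12,MAC,NOVA,female,0,4.0,1,T10
TU13,MAC,NOVA,male,0,4.0,1,T10
TU14,MAC,NOVA,female,0,4.0,1,T10
TU15,MAC,NOVA,male,0,4.0,1,T10
TU16,MAC,NOVA,female,0,4.0,1,T10
TU17,GUS,HOPE,male,0,2.0,1,T11
TU18,GUS,HOPE,female,0,2.0,1,T11
TU19,GUS,HOPE,male,0,2.0,1,T11
TU20,GUS,HOPE,female,0,2.0,1,T11
TU21,GUS,HOPE,male,0,2.0,1,T11
TU22,GUS,HOPE,female,0,2.0,1,T11
TU23,GUS,HOPE,male,0,2.0,1,T11
TU24,GUS,HOPE,female,0,2.0,1,T11
TU25,ELI,FAWN,male,0,1.5,1,T12
TU26,ELI,FAWN,female,0,1.5,1,T12
TU27,ELI,FAWN,male,0,1.5,1,T12
TU28,ELI,FAWN,female,0,1.5,1,T12
TU29,ELI,FAWN,male,0,1.5,1,T12
TU30,ELI,FAWN,female,0,1.5,1,T12
TU31,ELI,FAWN,male,0,1.5,1,T12
TU32,ELI,FAWN,female,0,1.5,1,T12
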