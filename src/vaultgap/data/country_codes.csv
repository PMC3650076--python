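alpha2,alpha3
US,USA
IN,IND
CN,CHN
JP,JPN
KR,KOR
RU,RUS
IT,ITA
DE,DEU
AU,AUS
CA,CAN
BR,BRA
ET,ETH
KE,KEN
MX,MEX
PT,PRT
PH,PHL
AR,ARG
NE,NER
IR,IRN
PK,PAK
TR,TUR
FR,FRA
GB,GBR
PL,POL
ES,ESP
BG,BGR
CL,CHL
HU,HUN
NP,NPL
UG,UGA
ZM,ZMB
UA,UKR
SK,SVK
UZ,UZB
KZ,KAZ
IL,ISR
RS,SRB
MA,MAR
PE,PER
TW,TWN
PG,PNG
NO,NOR
SE,SWE
DK,DNK
FI,FIN
IS,ISL
NL,NLD
BE,BEL
CH,CHE
AT,AUT
CZ,CZE
RO,ROU
GR,GRC
EG,EGY
NG,NGA
ZA,ZAF
GH,GHA
CI,CIV
SY,SYR
LB,LBN
MM,MMR
TH,THA
VN,VNM
ID,IDN
MY,MYS
BD,BGD
LK,LKA
AF,AFG
CO,COL
BO,BOL
EC,ECU
VE,VEN
UY,URY
PY,PRY
GT,GTM
CU,CUB
NZ,NZL
SN,SEN
ML,MLI
BF,BFA
TZ,TZA
MZ,MOZ
MW,MWI
ZW,ZWE
SD,SDN
DZ,DZA
TN,TUN
LY,LBY
MD,MDA
BY,BLR
GE,GEO
AM,ARM
AZ,AZE
TJ,TJK
KG,KGZ
TM,TKM
MN,MNG
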