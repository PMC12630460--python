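# Curated subset of WGSRPD Level-3 "botanical country" codes.
# Not exhaustive: codes absent from this list are accepted with a warning.
ABT
AFG
AGE
AGS
AGW
ALA
ALB
ALG
ALU
ANG
ARI
ARK
ASK
AUT
AZO
BAH
BAN
BEN
BER
BGM
BKN
BLZ
BOL
BOR
BOT
BRC
BUL
BUR
BZC
BZE
BZL
BZN
BZS
CAB
CAL
CAY
CBD
CHA
CLC
CLM
CLN
CLS
COL
COM
CON
COO
COR
COS
CPI
CPP
CPV
CRL
CUB
CZE
DEL
DEN
DJI
DOM
ECU
EGY
ELS
ERI
ETH
FIJ
FIN
FLA
FRA
FRG
GAB
GAL
GAM
GEO
GER
GHA
GIL
GRB
GRC
GUA
GUI
GUY
HAI
HAW
HON
HUN
ICE
IDA
ILL
IND
IOW
IRE
IRN
IRQ
ITA
IVO
JAM
JAP
JAW
KAN
KAZ
KEN
KOR
KTY
LAB
LAO
LBR
LBY
LES
LOU
MAI
MAN
MAS
MAU
MDG
MIC
MIN
MLI
MLW
MLY
MON
MOR
MOZ
MRQ
MTN
MXC
MXE
MXG
MXN
MXS
MXT
MYA
NAM
NAT
NBR
NCA
NDA
NEB
NEP
NET
NFK
NFL
NGA
NGR
NIC
NOR
NSC
NSW
NTA
NUE
NUN
NWC
NWG
NWJ
NWM
NWT
NWY
NZN
NZS
OHI
OKL
OMA
ONT
ORE
PAK
PAN
PAR
PEI
PEN
PER
PHI
POL
POR
PUE
QLD
QUE
REU
RHO
ROM
RUC
RUE
RUN
RUS
RUW
RWA
SAM
SAR
SAS
SAU
SCA
SCZ
SDA
SEN
SEY
SIC
SIE
SOA
SOL
SOM
SPA
SRL
SUD
SUL
SUM
SUR
SWE
SWI
TAN
TAS
TCI
TEN
TEX
THA
TOG
TON
TRT
TUN
TUR
UGA
URU
UTA
VAN
VEN
VER
VIC
VIE
VRG
WAS
WAU
WDC
WIS
WSA
WVA
WYO
YEM
YUK
ZAI
ZAM
ZIM
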