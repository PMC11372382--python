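country_code,country_name,subregion
ATG,Antigua and Barbuda,Non-Latin Caribbean
ARG,Argentina,Southern Cone
BHS,Bahamas,Non-Latin Caribbean
BRB,Barbados,Non-Latin Caribbean
BLZ,Belize,Central America Mexico and Latin Caribbean
BOL,Bolivia (Plurinational State of),Andean Area
BRA,Brazil,Southern Cone
CAN,Canada,North American
CHL,Chile,Southern Cone
COL,Colombia,Andean Area
CRI,Costa Rica,Central America Mexico and Latin Caribbean
CUB,Cuba,Central America Mexico and Latin Caribbean
DOM,Dominican Republic,Central America Mexico and Latin Caribbean
ECU,Ecuador,Andean Area
SLV,El Salvador,Central America Mexico and Latin Caribbean
GRD,Grenada,Non-Latin Caribbean
GTM,Guatemala,Central America Mexico and Latin Caribbean
GUY,Guyana,Non-Latin Caribbean
HTI,Haiti,Central America Mexico and Latin Caribbean
HND,Honduras,Central America Mexico and Latin Caribbean
JAM,Jamaica,Non-Latin Caribbean
MEX,Mexico,Central America Mexico and Latin Caribbean
NIC,Nicaragua,Central America Mexico and Latin Caribbean
PAN,Panama,Central America Mexico and Latin Caribbean
PRY,Paraguay,Southern Cone
PER,Peru,Andean Area
LCA,Saint Lucia,Non-Latin Caribbean
VCT,Saint Vincent and the Grenadines,Non-Latin Caribbean
SUR,Suriname,Non-Latin Caribbean
TTO,Trinidad and Tobago,Non-Latin Caribbean
USA,United States of America,North American
URY,Uruguay,Southern Cone
VEN,Venezuela (Bolivarian Republic of),Andean Area
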