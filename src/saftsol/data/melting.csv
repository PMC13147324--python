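id,T_SL_K,dH_SL_kJ_mol,dCp_SL_J_molK,approximated
ACF,426.0,49.3,115.7,true
ASP,409.0,32.6,79.6,true
ATN,424.5,36.6,86.2,true
BEN,451.9,44.5,98.5,true
BIF,434.5,63.8,146.8,true
BFZ,423.0,37.5,88.7,true
CIM,414.2,35.5,85.7,true
CIN,394.0,37.1,113.6,false
DAP,450.4,21.4,47.5,true
DPA,412.5,37.9,91.9,true
EST,527.1,45.1,85.6,true
FFB,354.0,33.5,124.3,false
IBU,350.2,25.5,50.3,false
MAC,503.1,71.2,141.5,true
NDO,403.4,53.0,131.4,true
NIM,422.2,47.4,112.3,true
PCM,441.6,28.6,99.8,false
RIV,505.6,50.2,99.3,true
RVC,420.8,30.1,71.6,true
TMP,358.6,16.4,45.8,true
g-IND,433.4,39.3,117.0,false
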