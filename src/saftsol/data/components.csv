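id,name,m_seg,sigma,u_kB,eps_AB_kB,kappa_AB,assoc_scheme,Mw
ACF,aceclofenac,8.68,3.21,317.5,2649.8,0.046,2B,354.2
ASP,aspirin,8.12,2.81,258.7,1825.5,0.008,2B,180.2
ATN,atenolol,9.22,2.85,316,2977.7,0.018,2B,266.3
BEN,benorilate,8.86,3.1,283.4,2661.8,0.003,2B,313.3
BIF,bifendate,9.31,3.39,294.9,0,0.01,2B,418.4
BFZ,bifonazole,7.57,3.56,319.7,0,0,none,310.4
CIM,cimetidine,7.74,3.24,352.4,2033.4,0.013,2B,252.3
CIN,cinnarizine,12.01,3.33,247.9,905.6,0.017,2B,368.5
DAP,dapsone,6.51,3.05,323.6,1992.6,0.023,2B,248.3
DPA,dipyridamole,10.76,3.33,298.62,1802.9,0.007,2B,504.6
EST,estrone,6.76,3.69,334.4,2270.1,0.014,2B,270.4
FFB,fenofibrate,9.26,3.53,275.9,0,0.02,2B,360.8
IBU,ibuprofen,7.28,3.33,295.4,2300.2,0.045,2B,206.3
MAC,mefenamic acid,8.98,2.89,271.8,2151,0.005,2B,241.3
NDO,nadolol,6.86,3.85,327.8,2225.8,0.009,2B,309.4
NIM,nimesulide,6.82,3.49,351.8,1094.8,0.011,2B,308.3
PCM,paracetamol,6.46,2.89,278.6,4338.2,0.009,2B,151.2
RIV,rivaroxaban,9.53,3.05,348.9,1600.4,0.01,2B,435.9
RVC,ropivacaine,6.00,3.88,313.4,1446.7,0.005,2B,274.4
TMP,tetramethylpyrazine,3.57,3.57,279.8,0,0,none,136.2
g-IND,gamma-indomethacin,9.52,3.13,305.0,1019.6,0.033,2B,357.8
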