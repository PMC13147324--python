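id,name,m_seg,sigma,u_kB,eps_AB_kB,kappa_AB,assoc_scheme,Mw,citation
WAT,water,1.0656,3.0007,366.51,2500.7,0.034868,2B,18.015,"Gross & Sadowski, Ind. Eng. Chem. Res. 41 (2002) 5510"
MeOH,methanol,1.5255,3.2300,188.90,2899.5,0.035176,2B,32.042,"Gross & Sadowski, Ind. Eng. Chem. Res. 41 (2002) 5510"
EtOH,ethanol,2.3827,3.1771,198.24,2653.4,0.032384,2B,46.069,"Gross & Sadowski, Ind. Eng. Chem. Res. 41 (2002) 5510"
1PrOH,1-propanol,2.9997,3.2522,233.40,2276.8,0.015268,2B,60.096,"Gross & Sadowski, Ind. Eng. Chem. Res. 41 (2002) 5510"
2PrOH,2-propanol,3.0929,3.2085,208.42,2253.9,0.024675,2B,60.096,"Gross & Sadowski, Ind. Eng. Chem. Res. 41 (2002) 5510"
1BuOH,1-butanol,2.7515,3.6139,259.59,2544.6,0.006692,2B,74.123,"Gross & Sadowski, Ind. Eng. Chem. Res. 41 (2002) 5510"
ACT,acetone,2.7447,3.2742,232.99,0,0,none,58.080,"Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244"
EA,ethyl acetate,3.5375,3.3079,230.80,0,0,none,88.106,"Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244"
TOL,toluene,2.8149,3.7169,285.69,0,0,none,92.141,"Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244"
BNZ,benzene,2.4653,3.6478,287.35,0,0,none,78.114,"Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244"
HEX,n-hexane,3.0576,3.7983,236.77,0,0,none,86.178,"Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244"
HEP,n-heptane,3.4831,3.8049,238.40,0,0,none,100.205,"Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244"
CHX,cyclohexane,2.5303,3.8499,278.11,0,0,none,84.162,"Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244"
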