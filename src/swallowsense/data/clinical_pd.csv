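id,gender,age,disease_duration,updrs3,updrs_axial,sdq,ledd,group
PT01,M,73,6,22,8,5,975,PD
PT02,M,76,11,35,11,7,712,PD
PT03,F,62,4,20,9,6,750,PD
PT04,M,77,10,54,13,10,350,PD
PT05,M,71,21,28,9,3,1219,PD
PT06,M,58,5,24,7,3,600,PD
PT07,F,74,14,39,16,6,1225,PD
PT08,F,67,14,30,12,2,1092,PD
PR02,F,74,3,27,4,13,300,PD
PR03,M,81,23,58,20,15,655,PD
PR04,M,70,15,45,16,9,1468,PD
PR05,M,57,7,21,5,3,832,PD
PR06,M,71,8,41,11,3,900,PD
PR07,M,74,16,33,11,9,1200,PD
PR08,M,58,13,28,16,4,1610,PD
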