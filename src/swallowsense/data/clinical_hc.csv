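id,gender,age,disease_duration,updrs3,updrs_axial,sdq,ledd,group
HC01,F,65,,,,1,,HC
HC02,M,65,,,,2,,HC
HC03,F,62,,,,6,,HC
HC04,M,65,,,,4,,HC
HC05,M,74,,,,1,,HC
HC06,F,68,,,,2,,HC
HC07,F,60,,,,3,,HC
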