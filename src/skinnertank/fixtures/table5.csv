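subject,condition,task,correct,total,accuracy_pct,sd_pct,p_text
1,,3v12,155,239,61.38,18.04,<0.001
1,,2v3,216,397,54.92,8.90,0.088
2,,3v12,246,395,58.85,13.62,<0.001
2,,2v3,297,532,54.26,9.20,0.008
3,,3v12,330,589,55.50,6.81,0.004
4,,3v12,125,181,67.67,11.94,<0.001
4,,2v3,319,559,55.90,5.74,<0.001
5,,3v12,191,283,56.64,21.96,<0.001
5,,2v3,379,697,55.00,6.50,<0.001
6,,3v12,239,382,62.23,12.46,<0.001
6,,2v3,202,391,52.10,7.33,0.544
7,,3v12,224,416,53.92,13.07,0.128
7,,2v3,147,334,43.70,7.93,0.033
8,,3v12,196,292,66.94,4.60,<0.001
8,,2v3,316,621,50.28,8.02,0.688
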