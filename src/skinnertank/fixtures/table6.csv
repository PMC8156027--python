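subject,condition,task,correct,total,accuracy_pct,sd_pct,p_text
1,,3v12,127,175,71.68,9.04,<0.001
1,,2v3,134,160,83.75,5.30,<0.001
2,,3v12,138,214,60.32,14.09,<0.001
2,,2v3,142,259,53.44,11.59,0.136
3,,3v12,148,212,60.51,13.89,<0.001
3,,2v3,207,382,54.13,5.03,0.113
4,,3v12,160,332,46.00,9.77,0.546
5,,3v12,136,196,66.28,14.73,<0.001
5,,2v3,114,250,44.46,7.78,0.184
6,,3v12,178,348,48.78,9.97,0.708
7,,3v12,195,339,56.14,6.63,0.007
8,,3v12,91,134,65.25,7.02,<0.001
8,,2v3,253,483,51.79,6.79,0.317
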