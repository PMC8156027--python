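subject,condition,task,correct,total,accuracy_pct,sd_pct,p_text
1,,3v12,21,24,87.50,5.89,<0.001
1,,2v3,19,24,79.17,5.89,0.007
1,,3v4,36,48,75.00,11.79,<0.001
1,,4v5,71,120,59.17,11.42,0.055
2,,3v12,68,96,70.83,4.45,<0.001
2,,2v3,18,24,75.00,23.57,0.023
2,,3v4,18,24,75.00,3.57,0.023
2,,4v5,68,120,56.67,14.59,0.171
3,,3v12,32,48,66.67,11.79,0.029
3,,2v3,32,48,66.67,9.62,0.029
3,,3v4,39,60,65.00,25.91,0.027
3,,4v5,68,120,56.67,13.49,0.171
4,,3v12,77,120,64.17,7.91,0.002
4,,2v3,19,24,79.17,5.89,0.007
4,,3v4,64,120,53.70,10.54,0.523
5,,3v12,33,48,68.75,14.23,0.013
5,,2v3,18,24,75.00,0.00,0.023
5,,3v4,57,84,67.86,8.91,0.001
5,,4v5,25,36,69.44,17.35,0.029
5,,5v6,61,120,50.83,10.72,0.927
6,,3v12,18,24,75.00,11.79,0.023
6,,2v3,22,24,91.67,11.79,<0.001
6,,3v4,18,24,75.00,11.79,0.023
6,,4v5,74,120,61.67,13.72,0.013
6,,5v6,62,120,51.67,11.65,0.784
7,,3v12,24,36,66.67,14.43,0.065
7,,2v3,39,60,65.00,13.69,0.027
7,,3v4,44,60,73.33,6.97,<0.001
7,,4v5,64,120,55.00,11.91,0.523
8,,3v12,32,48,66.67,13.61,0.029
8,,2v3,34,48,70.83,8.33,0.006
8,,3v4,60,120,50.00,13.61,1.000
9,,3v12,67,108,62.04,13.89,0.016
9,,2v3,18,24,75.00,11.79,0.023
9,,3v4,24,36,66.67,16.67,0.065
9,,4v5,63,120,52.50,13.64,0.648
10,,3v12,18,24,75.00,23.57,0.023
10,,2v3,50,72,69.44,4.30,0.001
11,,3v12,25,36,69.44,12.73,0.029
11,,2v3,56,84,66.67,11.79,0.003
11,,3v4,19,24,79.17,5.89,0.007
11,,4v5,18,24,75.00,0.00,0.023
11,,5v6,61,120,52.50,13.64,0.927
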