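subject,condition,task,correct,total,accuracy_pct,sd_pct,p_text
1,A,3v12,267,494,53.35,8.02,0.079
2,A,3v12,179,352,49.96,7.37,0.790
3,A,3v12,195,363,53.82,8.14,0.172
4,A,3v12,219,411,52.67,6.47,0.200
5,A,3v12,253,485,51.40,7.17,0.364
1,B,3v12,131,240,54.14,9.84,0.175
2,B,3v12,172,347,49.37,10.74,0.915
3,B,3v12,213,444,47.43,9.14,0.420
4,B,3v12,207,388,53.03,11.37,0.204
5,B,3v12,200,376,51.90,8.14,0.236
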