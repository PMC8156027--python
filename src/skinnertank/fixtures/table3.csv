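subject,condition,task,correct,total,accuracy_pct,sd_pct,p_text
1,,3v12,219,339,58.39,12.40,<0.001
1,,2v3,338,650,49.06,5.30,0.327
2,,3v12,170,328,51.68,7.64,0.544
3,,3v12,368,679,53.70,5.77,0.032
4,,3v12,385,745,51.10,8.10,0.379
5,,3v12,142,288,45.83,12.61,0.860
6,,3v12,230,470,48.11,9.92,0.678
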