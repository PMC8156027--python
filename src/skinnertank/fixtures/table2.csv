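subject,condition,task,correct,total,accuracy_pct,sd_pct,p_text
1,,3v12,268,523,50.52,7.19,0.600
1,,3v12_last6,150,289,51.07,8.04,0.556
2,,3v12,355,621,57.01,10.67,<0.001
2,,3v12_last6,134,223,60.51,9.42,0.003
3,,3v12,362,662,54.76,6.22,0.018
3,,3v12_last6,209,373,56.59,7.20,0.038
4,,3v12,475,839,55.82,6.88,<0.001
4,,3v12_last6,269,448,59.42,6.43,<0.001
5,,3v12,151,324,46.88,11.78,0.243
5,,3v12_last6,74,143,50.71,7.48,0.738
6,,3v12,301,570,53.04,6.04,0.191
6,,3v12_last6,163,297,54.58,6.72,0.104
7,,3v12,139,301,44.69,10.80,0.205
7,,3v12_last6,60,127,44.69,12.31,0.595
8,,3v12,209,423,49.64,9.58,0.846
8,,3v12_last6,87,164,50.43,8.67,0.482
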