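subject,condition,task,correct,total,accuracy_pct,sd_pct,p_text
1,,shape,190,374,48.33,7.66,0.796
2,,shape,277,498,54.20,12.96,0.014
2,,color,246,406,60.66,18.29,<0.001
2,,size,465,720,64.58,8.08,<0.001
2,,3v12,439,721,60.91,8.76,<0.001
2,,shape2,410,640,64.06,7.58,<0.001
3,,shape,142,204,65.64,19.46,<0.001
3,,color,141,160,88.13,0.88,<0.001
3,,size,204,275,73.77,4.95,<0.001
3,,3v12,492,791,62.19,5.50,<0.001
3,,shape2,445,787,56.38,7.94,<0.001
4,,shape,81,106,75.88,4.46,<0.001
4,,color,450,750,59.06,13.77,<0.001
4,,size,369,551,67.01,4.95,<0.001
4,,3v12,326,596,52.03,11.15,0.024
5,,shape,182,388,46.96,5.52,0.243
6,,shape,251,545,45.68,3.80,0.072
7,,shape,131,160,81.88,2.65,<0.001
7,,color,117,153,76.54,2.18,<0.001
7,,size,133,160,83.13,4.42,<0.001
7,,3v12,288,467,61.82,8.15,<0.001
7,,shape2,391,739,52.66,5.34,0.122
8,,shape,131,160,81.88,4.42,<0.001
8,,color,370,611,58.20,13.84,<0.001
8,,size,141,160,88.13,4.42,<0.001
8,,3v12,430,661,64.50,8.96,<0.001
8,,shape2,483,714,67.68,4.29,<0.001
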