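dosimeter_no,mean_dose_mGy,rel_sd_pct,n
1,0.25,33,6
2,0.33,27,6
3,0.52,20,6
4,0.48,22,6
5,0.53,20,6
6,0.73,17,6
7,0.81,16,6
8,3.86,7,6
9,4.04,7,6
10,7.11,5,6
11,6.53,5,6
12,10.4,4,6
13,7.71,5,6
14,4.09,7,6
15,4.66,6,6
16,4.25,6,6
17,6.15,5,6
18,6.45,5,6
19,7.33,5,6
20,3.40,7,6
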