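case_id,age,heavy_exertion,unacclimatized,onset_date,tropical_night,heat_wave,wbgt_max
1,41,1,0,,0,1,31.75
2,55,1,0,,0,1,32.59
3,66,1,0,,0,1,30.24
4,29,1,0,,1,1,30.62
5,54,1,0,,1,1,29.9
6,44,1,0,,1,1,31.76
7,49,1,0,,1,1,30.98
8,63,1,0,,1,1,31.29
9,50,1,0,,1,1,30.76
10,29,1,0,,1,1,32.29
11,53,1,0,,1,1,29.0
12,44,1,0,,1,1,29.97
13,46,1,0,,1,1,29.14
14,62,1,0,,1,1,31.89
15,45,1,1,,1,1,25.71
16,35,1,1,,1,1,30.37
17,54,1,1,,1,1,30.28
18,44,1,1,,1,1,31.27
19,56,1,1,,1,1,29.88
20,44,1,1,,1,1,30.77
21,56,1,1,,1,1,29.03
22,52,1,1,,1,1,30.48
23,45,1,1,,1,1,29.31
24,39,1,1,,1,1,30.78
25,39,1,1,,1,0,25.98
26,42,1,1,,1,0,29.29
27,54,1,1,,1,0,31.66
28,51,1,1,,1,0,30.09
29,49,1,1,,1,0,30.76
30,47,1,1,,1,0,28.85
31,64,1,1,,1,0,29.09
32,62,1,1,,1,0,27.46
33,51,1,1,,1,0,32.72
34,66,1,1,,1,0,29.57
35,47,1,0,,1,0,30.59
36,50,1,0,,0,0,29.73
37,60,1,0,,0,0,30.11
38,54,1,0,,0,0,30.39
39,49,1,0,,0,0,24.37
40,60,1,0,,0,0,23.43
41,59,1,0,,0,0,25.87
42,67,0,0,,1,1,32.59
43,56,0,0,,1,1,30.67
44,77,0,0,,1,1,30.53
45,37,0,1,,1,1,29.29
46,51,0,1,,0,0,30.72
47,71,0,0,,1,1,32.45
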