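# Synthetic reconstruction of the 2010 US single-year-of-age
# distribution from published five-year-bin totals (persons);
# uniform within bins, linear decline within the 85+ bin.
# NOT Census Bureau single-year data.
age,count
1,4040200
2,4040200
3,4040200
4,4040200
5,4069800
6,4069800
7,4069800
8,4069800
9,4069800
10,4135400
11,4135400
12,4135400
13,4135400
14,4135400
15,4408000
16,4408000
17,4408000
18,4408000
19,4408000
20,4317200
21,4317200
22,4317200
23,4317200
24,4317200
25,4220400
26,4220400
27,4220400
28,4220400
29,4220400
30,3992400
31,3992400
32,3992400
33,3992400
34,3992400
35,4036000
36,4036000
37,4036000
38,4036000
39,4036000
40,4178200
41,4178200
42,4178200
43,4178200
44,4178200
45,4541800
46,4541800
47,4541800
48,4541800
49,4541800
50,4459600
51,4459600
52,4459600
53,4459600
54,4459600
55,3933000
56,3933000
57,3933000
58,3933000
59,3933000
60,3363600
61,3363600
62,3363600
63,3363600
64,3363600
65,2487000
66,2487000
67,2487000
68,2487000
69,2487000
70,1855600
71,1855600
72,1855600
73,1855600
74,1855600
75,1463600
76,1463600
77,1463600
78,1463600
79,1463600
80,1148600
81,1148600
82,1148600
83,1148600
84,1148600
85,646235
86,605846
87,565456
88,525066
89,484676
90,444287
91,403897
92,363507
93,323118
94,282728
95,242338
96,201949
97,161559
98,121169
99,80779
100,40390
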