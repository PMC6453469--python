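# synthetic stand-in generated by cldmd.synthetic around the real
# alpha-synuclein sequence on a seeded claw-like trace (seed 20260101);
# emulates the shape of the experimental supplement, not its values
residue,deuteration
1,0.95
2,0.95
3,0.95
4,0.95
5,0.95
6,0.95
7,0.95
8,0.95
9,0.95
10,0.95
11,0.95
12,0.95
13,0.95
14,0.95
15,0.95
16,0.95
17,0.95
18,0.95
19,0.95
20,0.95
21,0.95
22,0.95
23,0.95
24,0.95
25,0.95
26,0.95
27,0.95
28,0.95
29,0.95
30,0.95
31,0.95
32,0.95
33,0.95
34,0.95
35,0.95
36,0.95
37,0.95
38,0.95
39,0.95
40,0.95
41,0.95
42,0.95
43,0.95
44,0.95
45,0.95
46,0.95
47,0.95
48,0.95
49,0.95
50,0.95
51,0.95
52,0.95
53,0.95
54,0.95
55,0.95
56,0.95
57,0.95
58,0.95
59,0.95
60,0.95
61,0.95
62,0.95
63,0.95
64,0.95
65,0.95
66,0.95
67,0.95
68,0.95
69,0.95
70,0.95
71,0.95
72,0.95
73,0.95
74,0.10
75,0.10
76,0.10
77,0.95
78,0.95
79,0.10
80,0.10
81,0.10
82,0.95
83,0.95
84,0.95
85,0.95
86,0.95
87,0.95
88,0.95
89,0.95
90,0.95
91,0.95
92,0.95
93,0.95
94,0.95
95,0.95
96,0.95
97,0.95
98,0.95
99,0.95
100,0.95
101,0.95
102,0.95
103,0.95
104,0.95
105,0.95
106,0.95
107,0.95
108,0.95
109,0.95
110,0.95
111,0.95
112,0.95
113,0.95
114,0.95
115,0.95
116,0.95
117,0.95
118,0.95
119,0.95
120,0.95
121,0.95
122,0.95
123,0.95
124,0.95
125,0.95
126,0.95
127,0.95
128,0.95
129,0.95
130,0.95
131,0.95
132,0.95
133,0.95
134,0.95
135,0.95
136,0.95
137,0.95
138,0.95
139,0.95
140,0.95
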