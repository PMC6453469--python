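# synthetic stand-in generated by cldmd.synthetic around the real
# alpha-synuclein sequence on a seeded claw-like trace (seed 20260101);
# emulates the shape of the experimental supplement, not its values
res_i,res_j,reagent
1,5,ABAS
6,18,ABAS
23,27,ABAS
32,37,ABAS
41,45,ABAS
56,60,ABAS
74,80,ABAS
80,86,ABAS
1,5,SDA
1,135,SDA
15,21,SDA
32,37,SDA
34,48,SDA
39,43,SDA
49,58,SDA
102,107,SDA
1,139,TATA
8,13,TATA
12,17,TATA
44,54,TATA
82,89,TATA
100,107,TATA
127,137,TATA
128,139,TATA
1,139,EDC
1,140,EDC
2,6,EDC
28,32,EDC
35,43,EDC
98,102,EDC
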