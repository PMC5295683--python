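# n=2704 folded=true
# human mtDNA diallelic segregating sites (rare-allele copy counts)
1	1231
2	542
3	298
4	170
5	149
6	95
7	66
8	67
9	35
10	33
11	28
12	21
13	17
14	24
15	16
16	22
17	15
18	19
19	13
20	17
21	10
22	13
23	14
24	8
25	5
26	15
27	13
28	10
29	5
30	5
31	8
32	10
33	7
34	5
35	8
36	9
37	8
38	2
39	8
40	1
41	3
42	5
43	5
44	7
45	5
46	1
47	6
48	4
49	1
50	1
51	3
52	2
53	2
54	1
55	5
56	2
57	1
58	4
59	1
60	3
61	4
62	3
63	2
64	1
65	3
66	1
67	1
68	1
69	2
70	1
72	1
74	1
76	1
77	2
78	1
79	1
81	1
83	3
84	4
85	3
86	6
87	1
88	1
89	1
90	1
91	1
94	1
95	2
96	3
98	2
104	1
110	1
111	1
127	1
128	1
129	2
131	2
132	2
133	1
134	1
135	1
138	2
139	1
144	1
147	3
149	3
150	1
152	1
156	1
174	1
176	1
204	1
213	1
218	1
234	1
235	1
244	1
264	1
272	1
299	1
347	2
390	1
444	1
505	1
550	1
604	1
610	1
720	1
724	1
777	1
867	1
933	1
943	1
944	1
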