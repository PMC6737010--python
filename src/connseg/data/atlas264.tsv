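roi_id	x	y	z	network
1	-66.0	-66.0	-66.0	Hand
2	-66.0	-66.0	-44.0	Hand
3	-66.0	-66.0	-22.0	Hand
4	-66.0	-66.0	0.0	Hand
5	-66.0	-66.0	22.0	Hand
6	-66.0	-66.0	44.0	Hand
7	-66.0	-66.0	66.0	Hand
8	-66.0	-44.0	-66.0	Hand
9	-66.0	-44.0	-44.0	Hand
10	-66.0	-44.0	-22.0	Hand
11	-66.0	-44.0	0.0	Hand
12	-66.0	-44.0	22.0	Hand
13	-66.0	-44.0	44.0	Hand
14	-66.0	-44.0	66.0	Hand
15	-66.0	-22.0	-66.0	Hand
16	-66.0	-22.0	-44.0	Hand
17	-66.0	-22.0	-22.0	Hand
18	-66.0	-22.0	0.0	Hand
19	-66.0	-22.0	22.0	Hand
20	-66.0	-22.0	44.0	Hand
21	-66.0	-22.0	66.0	Hand
22	-66.0	0.0	-66.0	Hand
23	-66.0	0.0	-44.0	Hand
24	-66.0	0.0	-22.0	Hand
25	-66.0	0.0	0.0	Hand
26	-66.0	0.0	22.0	Hand
27	-66.0	0.0	44.0	Hand
28	-66.0	0.0	66.0	Hand
29	-66.0	22.0	-66.0	Hand
30	-66.0	22.0	-44.0	Hand
31	-66.0	22.0	-22.0	Vis
32	-66.0	22.0	0.0	Vis
33	-66.0	22.0	22.0	Vis
34	-66.0	22.0	44.0	Vis
35	-66.0	22.0	66.0	Vis
36	-66.0	44.0	-66.0	Vis
37	-66.0	44.0	-44.0	Vis
38	-66.0	44.0	-22.0	Vis
39	-66.0	44.0	0.0	Vis
40	-66.0	44.0	22.0	Vis
41	-66.0	44.0	44.0	Vis
42	-66.0	44.0	66.0	Vis
43	-66.0	66.0	-66.0	Vis
44	-66.0	66.0	-44.0	Vis
45	-66.0	66.0	-22.0	Vis
46	-66.0	66.0	0.0	Vis
47	-66.0	66.0	22.0	Vis
48	-66.0	66.0	44.0	Vis
49	-66.0	66.0	66.0	Vis
50	-44.0	-66.0	-66.0	Vis
51	-44.0	-66.0	-44.0	Vis
52	-44.0	-66.0	-22.0	Vis
53	-44.0	-66.0	0.0	Vis
54	-44.0	-66.0	22.0	Vis
55	-44.0	-66.0	44.0	Vis
56	-44.0	-66.0	66.0	Vis
57	-44.0	-44.0	-66.0	Vis
58	-44.0	-44.0	-44.0	Vis
59	-44.0	-44.0	-22.0	Vis
60	-44.0	-44.0	0.0	Vis
61	-44.0	-44.0	22.0	Vis
62	-44.0	-44.0	44.0	Mouth
63	-44.0	-44.0	66.0	Mouth
64	-44.0	-22.0	-66.0	Mouth
65	-44.0	-22.0	-44.0	Mouth
66	-44.0	-22.0	-22.0	Mouth
67	-44.0	-22.0	0.0	Aud
68	-44.0	-22.0	22.0	Aud
69	-44.0	-22.0	44.0	Aud
70	-44.0	-22.0	66.0	Aud
71	-44.0	0.0	-66.0	Aud
72	-44.0	0.0	-44.0	Aud
73	-44.0	0.0	-22.0	Aud
74	-44.0	0.0	0.0	Aud
75	-44.0	0.0	22.0	Aud
76	-44.0	0.0	44.0	Aud
77	-44.0	0.0	66.0	Aud
78	-44.0	22.0	-66.0	Aud
79	-44.0	22.0	-44.0	Aud
80	-44.0	22.0	-22.0	DMN
81	-44.0	22.0	0.0	DMN
82	-44.0	22.0	22.0	DMN
83	-44.0	22.0	44.0	DMN
84	-44.0	22.0	66.0	DMN
85	-44.0	44.0	-66.0	DMN
86	-44.0	44.0	-44.0	DMN
87	-44.0	44.0	-22.0	DMN
88	-44.0	44.0	0.0	DMN
89	-44.0	44.0	22.0	DMN
90	-44.0	44.0	44.0	DMN
91	-44.0	44.0	66.0	DMN
92	-44.0	66.0	-66.0	DMN
93	-44.0	66.0	-44.0	DMN
94	-44.0	66.0	-22.0	DMN
95	-44.0	66.0	0.0	DMN
96	-44.0	66.0	22.0	DMN
97	-44.0	66.0	44.0	DMN
98	-44.0	66.0	66.0	DMN
99	-22.0	-66.0	-66.0	DMN
100	-22.0	-66.0	-44.0	DMN
101	-22.0	-66.0	-22.0	DMN
102	-22.0	-66.0	0.0	DMN
103	-22.0	-66.0	22.0	DMN
104	-22.0	-66.0	44.0	DMN
105	-22.0	-66.0	66.0	DMN
106	-22.0	-44.0	-66.0	DMN
107	-22.0	-44.0	-44.0	DMN
108	-22.0	-44.0	-22.0	DMN
109	-22.0	-44.0	0.0	DMN
110	-22.0	-44.0	22.0	DMN
111	-22.0	-44.0	44.0	DMN
112	-22.0	-44.0	66.0	DMN
113	-22.0	-22.0	-66.0	DMN
114	-22.0	-22.0	-44.0	DMN
115	-22.0	-22.0	-22.0	DMN
116	-22.0	-22.0	0.0	DMN
117	-22.0	-22.0	22.0	DMN
118	-22.0	-22.0	44.0	DMN
119	-22.0	-22.0	66.0	DMN
120	-22.0	0.0	-66.0	DMN
121	-22.0	0.0	-44.0	DMN
122	-22.0	0.0	-22.0	DMN
123	-22.0	0.0	0.0	DMN
124	-22.0	0.0	22.0	DMN
125	-22.0	0.0	44.0	DMN
126	-22.0	0.0	66.0	DMN
127	-22.0	22.0	-66.0	DMN
128	-22.0	22.0	-44.0	DMN
129	-22.0	22.0	-22.0	DMN
130	-22.0	22.0	0.0	DMN
131	-22.0	22.0	22.0	DMN
132	-22.0	22.0	44.0	DMN
133	-22.0	22.0	66.0	DMN
134	-22.0	44.0	-66.0	DMN
135	-22.0	44.0	-44.0	DMN
136	-22.0	44.0	-22.0	DMN
137	-22.0	44.0	0.0	DMN
138	-22.0	44.0	22.0	Sal
139	-22.0	44.0	44.0	Sal
140	-22.0	44.0	66.0	Sal
141	-22.0	66.0	-66.0	Sal
142	-22.0	66.0	-44.0	Sal
143	-22.0	66.0	-22.0	Sal
144	-22.0	66.0	0.0	Sal
145	-22.0	66.0	22.0	Sal
146	-22.0	66.0	44.0	Sal
147	-22.0	66.0	66.0	Sal
148	0.0	-66.0	-66.0	Sal
149	0.0	-66.0	-44.0	Sal
150	0.0	-66.0	-22.0	Sal
151	0.0	-66.0	0.0	Sal
152	0.0	-66.0	22.0	Sal
153	0.0	-66.0	44.0	Sal
154	0.0	-66.0	66.0	Sal
155	0.0	-44.0	-66.0	Sal
156	0.0	-44.0	-44.0	CO
157	0.0	-44.0	-22.0	CO
158	0.0	-44.0	0.0	CO
159	0.0	-44.0	22.0	CO
160	0.0	-44.0	44.0	CO
161	0.0	-44.0	66.0	CO
162	0.0	-22.0	-66.0	CO
163	0.0	-22.0	-44.0	CO
164	0.0	-22.0	-22.0	CO
165	0.0	-22.0	0.0	CO
166	0.0	-22.0	22.0	CO
167	0.0	-22.0	44.0	CO
168	0.0	-22.0	66.0	CO
169	0.0	0.0	-66.0	CO
170	0.0	0.0	-44.0	FP
171	0.0	0.0	-22.0	FP
172	0.0	0.0	0.0	FP
173	0.0	0.0	22.0	FP
174	0.0	0.0	44.0	FP
175	0.0	0.0	66.0	FP
176	0.0	22.0	-66.0	FP
177	0.0	22.0	-44.0	FP
178	0.0	22.0	-22.0	FP
179	0.0	22.0	0.0	FP
180	0.0	22.0	22.0	FP
181	0.0	22.0	44.0	FP
182	0.0	22.0	66.0	FP
183	0.0	44.0	-66.0	FP
184	0.0	44.0	-44.0	FP
185	0.0	44.0	-22.0	FP
186	0.0	44.0	0.0	FP
187	0.0	44.0	22.0	FP
188	0.0	44.0	44.0	FP
189	0.0	44.0	66.0	FP
190	0.0	66.0	-66.0	FP
191	0.0	66.0	-44.0	FP
192	0.0	66.0	-22.0	FP
193	0.0	66.0	0.0	FP
194	0.0	66.0	22.0	FP
195	0.0	66.0	44.0	DAN
196	0.0	66.0	66.0	DAN
197	22.0	-66.0	-66.0	DAN
198	22.0	-66.0	-44.0	DAN
199	22.0	-66.0	-22.0	DAN
200	22.0	-66.0	0.0	DAN
201	22.0	-66.0	22.0	DAN
202	22.0	-66.0	44.0	DAN
203	22.0	-66.0	66.0	DAN
204	22.0	-44.0	-66.0	DAN
205	22.0	-44.0	-44.0	DAN
206	22.0	-44.0	-22.0	VAN
207	22.0	-44.0	0.0	VAN
208	22.0	-44.0	22.0	VAN
209	22.0	-44.0	44.0	VAN
210	22.0	-44.0	66.0	VAN
211	22.0	-22.0	-66.0	VAN
212	22.0	-22.0	-44.0	VAN
213	22.0	-22.0	-22.0	VAN
214	22.0	-22.0	0.0	VAN
215	22.0	-22.0	22.0	unassigned
216	22.0	-22.0	44.0	unassigned
217	22.0	-22.0	66.0	unassigned
218	22.0	0.0	-66.0	unassigned
219	22.0	0.0	-44.0	unassigned
220	22.0	0.0	-22.0	unassigned
221	22.0	0.0	0.0	unassigned
222	22.0	0.0	22.0	unassigned
223	22.0	0.0	44.0	unassigned
224	22.0	0.0	66.0	unassigned
225	22.0	22.0	-66.0	unassigned
226	22.0	22.0	-44.0	unassigned
227	22.0	22.0	-22.0	unassigned
228	22.0	22.0	0.0	unassigned
229	22.0	22.0	22.0	unassigned
230	22.0	22.0	44.0	unassigned
231	22.0	22.0	66.0	unassigned
232	22.0	44.0	-66.0	unassigned
233	22.0	44.0	-44.0	unassigned
234	22.0	44.0	-22.0	unassigned
235	22.0	44.0	0.0	unassigned
236	22.0	44.0	22.0	unassigned
237	22.0	44.0	44.0	unassigned
238	22.0	44.0	66.0	unassigned
239	22.0	66.0	-66.0	unassigned
240	22.0	66.0	-44.0	unassigned
241	22.0	66.0	-22.0	unassigned
242	22.0	66.0	0.0	unassigned
243	22.0	66.0	22.0	unassigned
244	22.0	66.0	44.0	unassigned
245	22.0	66.0	66.0	unassigned
246	44.0	-66.0	-66.0	unassigned
247	44.0	-66.0	-44.0	unassigned
248	44.0	-66.0	-22.0	unassigned
249	44.0	-66.0	0.0	unassigned
250	44.0	-66.0	22.0	unassigned
251	44.0	-66.0	44.0	unassigned
252	44.0	-66.0	66.0	unassigned
253	44.0	-44.0	-66.0	unassigned
254	44.0	-44.0	-44.0	unassigned
255	44.0	-44.0	-22.0	unassigned
256	44.0	-44.0	0.0	unassigned
257	44.0	-44.0	22.0	unassigned
258	44.0	-44.0	44.0	unassigned
259	44.0	-44.0	66.0	unassigned
260	44.0	-22.0	-66.0	unassigned
261	44.0	-22.0	-44.0	unassigned
262	44.0	-22.0	-22.0	unassigned
263	44.0	-22.0	0.0	unassigned
264	44.0	-22.0	22.0	unassigned
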