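tunnel	bottleneck_radius	length	curvature
1	3.52	2.47	1.05
2	2.79	3.48	1.26
3	2.54	7.64	1.26
4	1.85	5.85	1.77
5	1.86	12.08	2.02
6	1.33	14.78	1.29
7	1.25	12.68	1.43
8	0.96	13.08	1.39
9	1.09	15.63	1.50
10	1.13	16.26	1.71
11	1.03	29.47	1.57
12	0.98	25.02	1.62
13	1.03	35.71	1.61
14	1.07	33.06	2.00
15	0.77	19.99	1.43
16	0.77	35.07	1.47
17	0.79	25.53	2.09
18	0.71	24.74	1.39
19	0.77	28.35	1.32
20	0.72	38.97	1.78
21	0.88	51.54	1.62
22	0.70	46.82	1.47
23	0.77	36.59	1.40
24	0.73	41.06	1.47
25	0.74	62.01	1.64
26	0.72	45.18	3.11
27	0.72	47.09	2.18
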