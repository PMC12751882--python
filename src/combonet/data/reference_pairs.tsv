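pair	d_pp	d_mm	d_pm	d_mp	d_plus_ref	d_minus_ref	label
1	3.55	3.27	4.17	4.08	-0.52	-0.81	synergism
2	2.80	3.91	4.38	4.51	-1.58	-0.47	synergism
3	3.63	3.08	4.50	4.06	-0.42	-0.97	synergism
4	4.21	3.92	4.35	3.84	0.36	0.08	synergism
5	2.87	3.48	4.43	4.07	-1.20	-0.59	synergism
6	2.70	3.05	4.02	3.94	-1.24	-0.89	synergism
7	3.81	3.81	3.83	3.94	-0.01	-0.02	antagonism
8	4.43	4.58	4.58	4.37	0.06	0.21	antagonism
9	5.31	3.41	5.07	5.15	0.24	-1.66	antagonism
10	3.96	4.32	4.36	4.20	-0.24	0.12	antagonism
11	3.96	4.46	4.61	4.40	-0.44	0.06	antagonism
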