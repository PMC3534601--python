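tissue	chrom_class	tot	f	m	pct_tot	pct_f	pct_m
Kidney	all	8153	4360	3793	18.1	9.67	8.41
Kidney	A	7825	4157	3668	18.2	9.67	8.54
Kidney	X	287	196	91	20.1	13.7	6.38
Kidney	Y	15	0	15	45.5	0	45.5
Kidney	NA	26	7	19	3.87	1.04	2.83
Liver	all	5193	2420	2773	11.5	5.37	6.15
Liver	A	4961	2296	2665	11.5	5.34	6.20
Liver	X	176	111	65	12.3	7.78	4.56
Liver	Y	15	0	15	45.5	0	45.5
Liver	NA	41	13	28	6.11	1.94	4.17
Lung	all	563	304	259	1.25	0.67	0.57
Lung	A	491	259	232	1.14	0.60	0.54
Lung	X	48	42	6	3.36	2.94	0.42
Lung	Y	16	0	16	48.5	0	48.5
Lung	NA	8	3	5	1.19	0.45	0.75
Striatum	all	747	541	206	1.66	1.20	0.46
Striatum	A	690	497	193	1.61	1.16	0.45
Striatum	X	38	37	1	2.66	2.59	0.07
Striatum	Y	12	0	12	36.4	0	36.4
Striatum	NA	7	7	0	1.04	1.04	0
Eye	all	106	65	41	0.24	0.14	0.09
Eye	A	49	28	21	0.11	0.07	0.05
Eye	X	38	36	2	2.66	2.52	0.14
Eye	Y	17	0	17	51.5	0	51.5
Eye	NA	2	1	1	0.30	0.15	0.15
Hippocampus	all	50	26	24	0.11	0.06	0.05
Hippocampus	A	8	2	6	0.02	0.00	0.01
Hippocampus	X	25	23	2	1.75	1.61	0.14
Hippocampus	Y	16	0	16	48.5	0	48.5
Hippocampus	NA	1	1	0	0.15	0.15	0
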