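tissue	xbar1	rn	rt	r_walk	d_scale	n_sc	m_sc	risk	dev
BLCA	140.61	57.53	34.68	48.40	0.0512	.	.	.	.
BRCA	137.37	20.97	31.66	84.74	0.0450	8.7e9	4.3	0.09228	0.03427
COAD	155.89	11.71	28.53	115.65	0.0526	2e8	73	0.04264	0.01504
ESCA	138.70	64.28	35.79	38.63	0.0710	6.65e6	33.18	0.00412	0.01378
HNSC	123.50	27.74	23.54	72.22	0.0549	1.85e7	21.15	0.01527	0.00578
KIRC	171.81	28.70	36.01	107.09	0.0679	.	.	.	.
KIRP	163.42	19.90	27.78	115.74	0.0768	.	.	.	.
LIHC	134.67	20.48	45.23	68.96	0.0461	3.01e9	0.9125	0.00397	0.00310
LUAD	145.33	13.52	32.06	99.75	0.0581	1.22e9	0.07	0.01610	0.00847
LUSC	194.49	11.62	36.65	146.22	0.0522	.	.	.	.
PRAD	91.33	31.31	32.17	27.85	0.0523	2.1e8	3	0.13712	0.07730
READ	168.05	22.90	28.81	116.34	0.0521	.	.	.	.
STAD	136.97	27.14	43.24	66.59	0.0455	.	.	.	.
THCA	112.55	20.02	39.85	52.67	0.0532	8.25e7	0.087	0.00649	0.00442
UCEC	171.38	38.24	22.14	111.00	0.0439	.	.	.	.
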