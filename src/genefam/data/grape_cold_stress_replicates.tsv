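# Published cold-stress microarray replicate intensities (RMA-normalized) for
# differentially expressed grape bHLH genes, with the means, fold changes and
# p-values as printed in the source publication's DE table (GSE31594 contrasts).
timepoint	gene_id	ck1	ck2	ck3	ck_mean_printed	cold1	cold2	cold3	cold_mean_printed	fold_printed	p_printed
1h	VvbHLH021	2.10	14.28	26.61	14.33	11.89	86.70	29.95	42.85	2.99	0.16
1h	VvbHLH039	0.73	3.78	8.47	4.33	12.17	15.49	24.80	17.49	4.04	0.01
1h	VvbHLH045	62.18	42.87	44.08	49.71	162.72	176.20	239.47	192.80	3.88	0.02
1h	VvbHLH047	445.19	361.14	489.53	431.95	618.86	1104.60	831.11	851.52	1.97	0.07
1h	VvbHLH061	1.27	1.11	2.64	1.67	0.69	1.57	5.86	2.71	1.62	0.23
1h	VvbHLH066	187.19	192.55	228.94	202.89	214.10	361.45	342.72	306.09	1.51	0.06
1h	VvbHLH068	1.93	2.05	4.95	2.98	9.26	2.56	16.76	9.53	3.20	0.09
4h	VvbHLH021	9.10	17.13	8.83	11.69	256.28	174.36	66.27	165.64	7.51	0.07
4h	VvbHLH045	55.38	18.50	49.49	41.13	75.06	89.14	92.29	85.50	1.86	0.16
4h	VvbHLH007	298.12	276.57	280.45	285.05	1175.30	925.11	494.27	864.89	1.76	0.05
4h	VvbHLH047	249.06	375.78	305.60	310.15	1369.50	950.03	649.32	989.62	3.19	0.05
4h	VvbHLH015	67.87	71.65	47.21	62.24	305.80	252.29	119.51	225.87	2.53	0.04
8h	VvbHLH021	3.91	3.85	1.39	3.05	158.36	155.58	181.99	165.31	54.16	0.00
8h	VvbHLH083	32.09	59.85	32.27	41.40	80.60	45.14	66.48	64.07	1.55	0.18
8h	VvbHLH046	28.12	31.90	48.93	36.32	72.78	60.65	70.58	68.00	1.87	0.02
8h	VvbHLH090	217.47	296.32	293.81	269.20	450.02	458.91	332.50	413.81	1.54	0.06
8h	VvbHLH052	217.47	296.32	293.81	269.20	450.02	458.91	332.50	413.81	1.54	0.06
8h	VvbHLH047	321.52	387.41	271.73	326.89	1086.20	857.72	1041.80	995.24	3.04	0.01
8h	VvbHLH065	167.85	238.48	299.32	235.22	346.41	490.64	268.64	368.56	1.57	0.13
8h	VvbHLH079	167.85	238.48	299.32	235.22	346.41	490.64	268.64	368.56	1.57	0.13
8h	VvbHLH066	171.62	177.90	179.35	176.29	561.44	480.46	539.36	527.09	2.99	0.00
8h	VvbHLH068	3.14	8.76	9.52	7.14	10.97	9.32	11.98	10.76	1.51	0.12
8h	VvbHLH015	58.75	65.04	58.58	60.79	323.91	251.12	170.73	248.59	4.09	0.03
8h	VvbHLH011	1558.90	1958.30	1886.10	1801.10	3256.80	2740.20	3764.40	3253.80	1.81	0.03
8h	VvbHLH029	155.24	117.41	84.02	118.89	205.26	203.01	288.18	232.15	1.95	0.07
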