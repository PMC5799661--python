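# Published Ka/Ks (omega) values for the member pairs of the nine triplicated
# gene groups of the grape bHLH family.
group	gene_a	gene_b	omega
1	VvbHLH025	VvbHLH040	0.1814
1	VvbHLH054	VvbHLH040	0.2561
2	VvbHLH058	VvbHLH020	0.1500
2	VvbHLH032	VvbHLH020	0.1488
3	VvbHLH063	VvbHLH001	0.1958
3	VvbHLH077	VvbHLH001	0.1533
4	VvbHLH093	VvbHLH082	0.2203
4	VvbHLH076	VvbHLH082	0.2293
5	VvbHLH060	VvbHLH006	0.1974
5	VvbHLH074	VvbHLH006	0.2618
6	VvbHLH068	VvbHLH007	0.0497
6	VvbHLH009	VvbHLH007	0.0113
7	VvbHLH088	VvbHLH090	0.2519
7	VvbHLH052	VvbHLH090	0.2819
8	VvbHLH053	VvbHLH039	0.2762
8	VvbHLH056	VvbHLH039	0.4034
9	VvbHLH072	VvbHLH070	0.1978
9	VvbHLH071	VvbHLH070	0.2605
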