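rank	betweenness	closeness	bottleneck
1	DLG4	DLG4	DLG4
2	SMC2	GRIN2B	DYNC1H1
3	DYNC1H1	GRIN2A	SMC2
4	PLCG1	GRIN1	PLCG1
5	GRIN2B	CAMK2A	CAMK2A
6	GRIN2A	PLCG1	RHOG
7	RHOG	DYNC1H1	NF2
8	SMC1A	RHOG	SMC1A
9	GRM1	LRRC7	GRIN2A
10	NF2	GRIA1	GRM1
11	GRIN1	GRM1	HRSP12
12	NCAPH	DLG2	GRIN2B
13	CAMK2A	DYNLL1	LRRC7
14	SOX9	SMC2	RAD21
15	CHEK1	SMC1A	GRIN1
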