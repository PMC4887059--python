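rank	betweenness	closeness	bottleneck
1	HEATR1	MACF1	ARAF
2	IGF1R	MAPK9	MAPK9
3	MAPK9	IGF1R	PLEC
4	ARAF	SPTA1	MSN
5	XRN1	PRKCE	HEATR1
6	PRKCE	XRN1	IGF1R
7	CPS1	DSP	CPS1
8	PLEC	ARAF	SPTA1
9	MSN	PLEC	UTP20
10	MTOR	HEATR1	RICTOR
11	MACF1	CPS1	MTOR
12	UTP20	MSN	PIK3R3
13	SPTA1	NRXN2	DSP
14	DSP	COL17A1	COL17A1
15	MAPK6	MAPK6	PRKCE
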