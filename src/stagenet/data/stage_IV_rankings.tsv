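rank	betweenness	closeness	bottleneck
1	GSK3B	GSK3B	GSK3B
2	AKT1	PXN	AKT1
3	PXN	AKT1	HSPA5
4	GGT1	VEGFA	CHKB
5	SFN	PLCG1	GGT1
6	PPIF	EIF2B5	PXN
7	GNAI2	CHKB	SFN
8	CHKB	GNAI2	PLCG1
9	HSPA5	FLT1	EIF2B5
10	EIF2B5	HSPA5	QARS
11	PLCG1	SFN	SSR4
12	SF3B3	GGT1	GNAI2
13	IARS	SF3B1	HECW1
14	NTRK2	ITGAV	NTRK2
15	MAGI1	ITGA9	SF3B3
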