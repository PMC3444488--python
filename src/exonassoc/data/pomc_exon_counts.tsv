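site_id	exon	region	dbsnp	aa_case_n	aa_case_N	ea_case_n	ea_case_N	aa_ctrl_n	aa_ctrl_N	ea_ctrl_n	ea_ctrl_N	effect
c.61A>G	1	FIVE_UTR	rs139229417	6	270	0	260	2	208	1	292	.
c.259G>A	3	FIVE_UTR	.	1	292	0	274	0	210	0	318	.
c.267C>T	3	CDS	.	0	292	0	274	0	210	1	318	missense P2S
c.281C>T	3	CDS	rs8192605	0	292	4	274	0	210	4	318	synonymous C6C
c.343G>A	3	CDS	.	0	292	0	274	0	210	1	318	nonsense W27stop
c.421A>G	4	CDS	rs28932470	2	258	0	242	0	208	1	292	missense D53G
c.432G>T	4	CDS	.	0	258	0	242	1	208	0	292	nonsense E57stop
c.524C>A	4	CDS	.	2	258	0	242	0	208	0	292	missense F87L
c.545C>T	4	CDS	rs28930368	0	258	4	242	0	208	2	292	synonymous S94S
c.560_561insAGCAGCGGC	4	CDS	rs10654394	66	258	16	242	59	208	14	292	9-bp insertion SSG
c.609C>T	4	CDS	rs34650613	0	258	0	242	0	208	1	292	synonymous L116L
c.656C>A	4	CDS	.	1	258	0	242	0	208	0	292	synonymous G131G
c.685T>G	4	CDS	.	1	288	0	266	0	212	0	314	missense M141R
c.840G>T	4	CDS	.	1	288	0	266	0	212	0	314	missense G193C
c.846G>A	4	CDS	rs141309351	2	288	0	266	1	212	0	314	missense A195T
c.848C>A	4	CDS	rs2071345	0	288	4	266	0	212	2	314	synonymous A195A
c.867_868insGGGCCC	4	CDS	.	0	288	1	266	0	212	0	314	6-bp insertion AG
c.904A>G	4	CDS	rs80326661	0	288	1	266	0	212	1	314	missense E214G
c.969C>G	4	CDS	rs28932472	0	288	0	266	0	212	1	314	missense R236G
c.989C>A	4	CDS	.	0	288	0	266	0	212	1	314	synonymous T242T
c.1095delT	4	THREE_UTR	.	0	302	0	282	0	222	1	324	.
c.1130C>T	4	THREE_UTR	rs1042571	35	302	60	282	31	222	68	324	.
c.1187A>G	4	THREE_UTR	.	0	302	0	282	0	222	1	324	.
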