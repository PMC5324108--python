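rsid	chromosome	risk_allele	raf	published_or
rs10752881	1	A	0.76	1.07
rs6691170	1	T	0.31	1.06
rs10936599	3	C	0.19	1.04
rs1321311	6	C	0.30	1.10
rs7758229	6	T	0.67	1.28
rs16892766	8	C	0.39	1.27
rs6983267	8	G	0.82	1.27
rs10795668	10	G	0.73	1.15
rs4948317	10	C	0.30	1.10
rs3802842	11	C	0.08	1.11
rs3824999	11	G	0.13	1.08
rs10879357	12	G	0.50	1.25
rs11169552	12	C	0.82	1.09
rs7315438	12	T	0.41	1.11
rs4444235	14	C	0.43	1.11
rs9929218	16	G	0.46	1.10
rs4939827	18	T	0.27	1.20
rs10411210	19	C	0.31	1.15
rs4925386	20	C	0.58	1.08
rs961253	20	A	0.28	1.12
rs5934683	X	C	0.57	1.07
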