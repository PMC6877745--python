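exon	site	hgvs_c	in_vitro	gnomad_alleles	clinvar	published_pvs1	published_pm2	published_class
1	donor	c.158+1G>T	No	0	Likely pathogenic (*)	PVS1	Yes	Likely pathogenic
2	acceptor	c.159-2A>G	No	1	Not reported	PVS1_strong	Yes	Likely pathogenic
2	acceptor	c.159-1G>T	No	0	Likely pathogenic (**)	PVS1_strong	Yes	Likely pathogenic
2	donor	215+2T>C	No	0	Likely pathogenic (*)	PVS1_strong	Yes	Likely pathogenic
3	acceptor	c.216-1G>A	No	0	Not reported	PVS1	Yes	Likely pathogenic
3	donor		No	0	Not reported	PVS1	Yes	Likely pathogenic
4	acceptor	c.365-1G>T	No	0	Likely pathogenic (*)	PVS1_strong	Yes	Likely pathogenic
4	acceptor	c.365-2A>G	No	1	Not reported	PVS1_strong	Yes	Likely pathogenic
4	donor	c.1314+1G>A	No	1	Likely pathogenic (**)	PVS1_strong	Yes	Likely pathogenic
5	acceptor	c.1315-2A>G	Δ(E5) with RT-PCR E4-E6	1	Not reported	PVS1_strong	Yes	Likely pathogenic
5	donor	c.1395+1dup	No	0	Likely pathogenic (**)	PVS1_moderate	Yes	Uncertain significance
6	acceptor		No	0	Not reported	PVS1	Yes	Likely pathogenic
6	donor	c.1568+2T>C	No	0	Likely pathogenic (*)	PVS1	Yes	Likely pathogenic
7	acceptor		No	0	Not reported	PVS1	Yes	Likely pathogenic
7	donor	c.1677+1G>C	No	0	Likely pathogenic (*)	PVS1	Yes	Likely pathogenic
7	donor	c.1677+1G>A	No	1	Not reported	PVS1	Yes	Likely pathogenic
8	acceptor	c.1678-1G>T	No	2	Not reported	PVS1	Yes	Likely pathogenic
8	donor	c.1810+1G>A	No	0	Likely pathogenic (*)	PVS1	Yes	Likely pathogenic
8	donor	c.1810+2T>G	No	0	Likely pathogenic (**)	PVS1	Yes	Likely pathogenic
9	acceptor	c.1811-1G>A	No	0	Pathogenic (*)	PVS1_strong	Yes	Likely pathogenic
9	donor	c.1903+1G>A	No	1	Not reported	PVS1_strong	Yes	Likely pathogenic
9	donor	c.1903+1G>T	No	0	Likely pathogenic (*)	PVS1_strong	Yes	Likely pathogenic
10	acceptor	c.1904-2A>T	No	0	Likely pathogenic (*)	PVS1_strong	Yes	Likely pathogenic
10	donor	c.2001+1G>T	No	1	Uncertain significance (*)	PVS1_strong	Yes	Likely pathogenic
10	donor	c.2001+1G>C	No	0	Likely pathogenic (**)	PVS1_strong	Yes	Likely pathogenic
10	donor	c.2001+1G>A	No	0	Uncertain significance (*)	PVS1_strong	Yes	Likely pathogenic
10	donor	c.2001+2T>C	No	1	Not reported	PVS1_strong	Yes	Likely pathogenic
11	acceptor	c.2002-2A>G	No	1	Not reported	PVS1_strong	Yes	Likely pathogenic
11	acceptor	c.2002-2A>C	No	0	Likely pathogenic(1); uncertain significance(1) (*)	PVS1_strong	Yes	Likely pathogenic
11	acceptor	c.2002-2A>T	No	0	Likely pathogenic(1); uncertain significance(1) (*)	PVS1_strong	Yes	Likely pathogenic
11	acceptor	c.2002-1G>A	No	1	Likely pathogenic (*)	PVS1_strong	Yes	Likely pathogenic
11	acceptor	c.2002-1G>C	No	0	Likely pathogenic (*)	PVS1_strong	Yes	Likely pathogenic
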