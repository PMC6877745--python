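exon	c_start	c_end
1	1	158
2	159	215
3	216	364
4	365	1314
5	1315	1395
6	1396	1568
7	1569	1677
8	1678	1810
9	1811	1903
10	1904	2001
11	2002	2334
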