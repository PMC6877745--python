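event_code	r_description	functional	novel	NS|lab1|LCL	RS|lab1|LCL	TRS|lab2|LCL	RP|lab4|LCL	TRS|davy2017|LCL	RP|studyB|PBL	RS|lab3|breast	RP|lab4|breast	RP|studyB|breast_tumor	RS|lab3|fimbria	RP|lab4|ovary	RP|studyC|cell_line	RP|studyD|fetal_sympathetic_ganglia	RP|studyD|neuroblastoma	RP|studyE|hela	RP|studyF|colon_cancer	RP|studyG|colon_cancer	RP|studyE|trophoblasts
Full length	-	IF	no	+	N	N	+	N	+	N	-	+	N	-	+	+	+	+	+	+	+
Δ(E1_E4p)	r.155_?del	?	no	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
Δ(E1q4)	r.155_158del	FS	no	-	+	+	+	+	-	+	+	-	-	+	-	+	-	-	-	-	-
Δ(E1q4,E4)	r.155_158+365_1314del	IF	no	-	N	N	-	N	-	N	-	-	N	-	-	+	-	-	-	-	-
IVS1+4279▼98	r.158_159ins158+4279_158+4376	FS	no	-	+	+	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E2)	r.159_215del	IF	no	-	-	+	-	-	-	-	-	-	-	-	-	-	-	+	+	-	-
Δ(E2q)	r.212_215del	FS	no	-	-	+	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E2_E3)	r.159_364del	FS	no	-	+	+	+	+	-	+	+	-	+	+	+	+	+	+	-	+	+
Δ(E2,E4_E9)	r.159_215+365_1903del	IF	yes	-	N	N	+	N	-	N	+	-	N	+	-	-	-	-	-	-	-
Δ(E2_E4)	r.159_1314del	FS	no	+	+	+	+	-	+	-	+	+	-	-	-	+	+	-	+	-	-
Δ(E2_E4,E7)	r.159_1314+1569_1677del	FS	no	-	N	N	-	N	-	N	-	-	N	-	-	-	-	-	+	-	-
Δ(E2_E4,E8)	r.159_1314+1678_1810del	FS	no	+	N	N	-	N	-	N	-	-	N	-	-	-	-	-	+	-	-
Δ(E2_E4,E8_E9)	r.159_1314+1678_1903del	FS	no	-	N	N	-	N	-	N	-	-	N	-	-	-	-	-	+	-	-
Δ(E2_E4,E8p)	r.159_1314+1678_?del	?	no	-	N	N	-	N	-	N	-	-	N	-	-	+	-	-	-	-	-
Δ(E2_E5)	r.159_1395del	FS	no	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-
Δ(E2_E6)	r.159_1568del	IF	no	+	-	+	-	-	+	-	-	+	-	-	+	+	+	+	+	+	+
Δ(E2_E6,E8)	r.159_1568+1678_1810del	FS	no	-	N	N	-	N	+	N	-	+	N	-	-	-	-	-	-	-	-
Δ(E2_E6,E8_E9)	r.159_1568+1678_1903del	FS	no	-	N	N	+	N	-	N	-	-	N	-	-	+	-	-	-	-	-
Δ(E2_E7)	r.159_1677del	FS	yes	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E2_E9)	r.159_1903del	FS	no	+	-	+	+	+	+	-	+	+	-	+	+	+	+	+	+	+	+
IVS2-780▼99	r.215_216ins216-780_216-682	IF	no	-	+	+	+	+	-	-	+	-	-	+	-	-	-	-	-	-	-
Δ(E3)	r.216_364del	FS	no	+	+	+	+	+	-	+	+	-	+	+	-	-	+	-	+	+	-
Δ(E3_E4)	r.216_1314del	FS	no	+	+	+	+	+	+	-	+	+	-	+	-	-	-	-	+	-	-
Δ(E3_E4,E7)	r.216_1314+1569_1677del	FS	yes	+	N	N	-	N	-	N	-	-	N	-	-	-	-	-	-	-	-
Δ(E3_E4,E8)	r.216_1314+1678_1810del	FS	no	-	N	N	-	N	-	N	-	-	N	-	-	-	+	-	-	-	-
Δ(E3_E5)	r.216_1395del	FS	no	-	-	+	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-
Δ(E3,E5_E9)	r.216_364+1315_1903del	IF	no	-	N	N	-	N	-	N	-	-	N	-	-	-	+	-	-	-	-
Δ(E3_E6)	r.216_1568del	IF	no	+	+	+	+	-	+	-	+	+	-	-	+	+	+	+	+	+	-
Δ(E3_E6,E8)	r.216_1568+1678_1810del	FS	no	-	N	N	-	N	+	N	-	+	N	-	-	-	-	-	-	-	-
Δ(E3_E7)	r.216_1677del	FS	no	+	-	+	+	-	-	-	-	-	-	+	-	-	+	-	-	-	-
Δ(E3_E9)	r.216_1903del	FS	no	+	-	+	+	-	-	-	-	-	-	-	-	-	+	-	+	-	-
Δ(E3q_E10)	r.361_2001del	IF	no	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-
Δ(E4)	r.365_1314del	FS	no	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	-
Δ(E4q137)	r.1178_1314del	FS	yes	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E4q408)	r.907_1314del	IF	no	-	+	+	+	+	-	-	+	-	-	+	+	-	+	-	+	+	-
Δ(E4int104)	r.718_821del	FS	yes	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E4int695)	r.472_1166del	FS	yes	-	+	+	+	-	-	-	-	-	-	+	-	-	-	-	-	-	-
Δ(E4,E6p)	r.365_?	?	no	-	N	N	-	N	-	N	-	-	N	-	-	-	+	-	-	-	-
Δ(E4_E6)	r.365_1568del	FS	no	-	+	+	+	-	-	-	-	-	-	+	-	+	-	-	-	-	-
Δ(E4q,E6q)	r.?_?	?	no	-	N	N	-	N	-	N	-	-	N	-	-	-	+	-	-	-	-
Δ(E4_E7)	r.365_1677del	FS	no	-	-	+	-	+	-	-	-	-	-	-	-	-	-	-	+	-	-
Δ(E4,E8_E9)	r.365_1314+1678_1903del	IF	no	+	N	N	-	N	-	N	-	-	N	-	-	-	+	-	+	-	-
Δ(E4_E9)	r.365_1903del	IF	no	+	-	+	+	-	-	-	+	-	-	-	+	-	+	+	+	+	+
IVS4-828▼38	r.1314_1315ins1315-828_1315-791	FS	yes	-	+	+	+	-	-	-	+	-	-	+	-	-	-	-	-	-	-
Δ(E5)	r.1315_1395del	IF	yes	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E5_E9)	r.1315_1903del	FS	yes	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E5_E10)	r.1315_2001del	IF	yes	-	-	-	+	-	-	-	+	-	-	+	-	-	-	-	-	-	-
▼(I5q3)	r.1395_1396ins1395+1_1395+3	IF	yes	-	+	+	+	-	-	-	+	-	-	+	-	-	-	-	-	-	-
Δ(E6q2)	r.1567_1568del	FS	yes	-	+	-	+	-	-	-	+	-	-	+	-	-	-	-	-	-	-
IVS6+4684▼67	r.1568_1569ins1568+4684_1568+4750	FS	yes	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E7)	r.1569_1677del	FS	no	+	+	+	+	+	-	-	+	-	-	+	-	-	-	-	-	-	-
Δ(E7p35)	r.1569_1603del	FS	yes	-	+	+	+	-	-	-	+	-	-	+	-	-	-	-	-	-	-
Δ(E7_E9)	r.1569_1903del	FS	no	-	-	+	-	+	-	+	-	-	+	-	-	-	-	-	+	-	-
▼(I7q4)	r.1677_1678ins1677+1_1677+4	FS	yes	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E8)	r.1678_1810del	FS	no	-	+	+	+	+	-	-	+	-	-	+	-	-	-	-	+	-	-
Δ(E8_E9)	r.1678_1903del	FS	no	-	+	+	-	+	-	-	-	-	-	-	-	-	-	-	+	-	-
Δ(E9)	r.1811_1903del	IF	yes	-	-	-	+	-	-	-	+	-	-	+	-	-	-	-	-	-	-
Δ(E9p30)	r.1811_1840del	IF	yes	-	+	+	+	-	-	-	+	-	-	+	-	-	-	-	-	-	-
▼(I9q4)	r.1903_1904ins1903+1_1903+4	FS	yes	-	+	+	+	-	-	-	+	-	-	-	-	-	-	-	-	-	-
IVS9+5946▼1015	r.1903_1904ins1903+5946_1904+6960	FS	no	-	+	+	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-
IVS9-6318▼92	r.1903_1904ins1904-6318_1904-6227	FS	yes	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Δ(E10q4)	r.1998_2001del	FS	no	-	-	+	+	+	-	-	+	-	-	+	-	-	-	-	-	-	-
IVS10+131▼46	r.2001_2002ins2001+131_2001+176	FS	no	-	+	+	+	+	-	-	+	-	-	+	-	-	-	-	-	-	-
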