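peak_center	fat	motif_center	motif_strand	motif	locus	intragenic	likely_false_positive	expr_wt	expr_dflia	sig_dflia
265447	24	265472	-	GATGAATGCGCTGTGTATTGCCGATAAC	(yafY)ykfB	1	0	118	42	1
426893	5	426874	+	AAGGGAATTGCCGTGTTAAACCGTTATC	(secD)	1	0	183	170	0
669828	10	669799	+	TAAAGATTTCATATCAACCGTCGATAAA	(holA)	1	0	190	170	0
788978	2	789005	-	TAAAGTTCGCGTGATGGCAGCCGATTAT	(galK)	1	0	232	224	0
794226	32	794199	+	TCAACTTCCTGCTTTTCCTGCCGATATT	modABC	0	0	182	61	1
815234	4	815204	+	TCAACTCACGCCCCAGATTGCCGATATA	(ybhK)	1	0	46	46	0
816109	2	816141	-	TAGAGTGTTTAGTGGTTATGCCGATACT	ybhK	0	0	46	46	0
946162	2	946134	+	TATGCTAATGCAGAATTTCTCCGATAAT	(ycaD)ycaM	1	0	7	7	0
1030917	1	1030887	+	TCTGGAACCCTTTCGGGTCGCCGGTTTT	(serT)hyaA	1	0	0	0	0
1049918	2	1049983	-	TAAGGAAATTGTTACGAAAGCTATTAAT	insB-4/cspH_convergent	0	1
1129384	48	1129409	-	TAAAGATTACCCGTCCCTTGCCGATAAA	flgMN	0	0	451	318	0
1137565	47	1137556	+	TCAAGTCCGGCGGGTCGCTGCCGATAAT	flgKL	0	0	318	138	0
1241331	2	1241357	-	TAAGTAAAACGCTGTCTCTGCCGCTAAT	cvrA	0	0	43	28	0
1243779	67	1243800	-	TTAAGTTTTGTTAACTGTGACCGATAAA	ycgR	0	0	104	0	1
1490461	23	1490443	+	TAAGTAATTACCGTCAAGTGCCGATGAC	trg	0	0	108	4	1
1512636	3	1512671	-	GCTGGGAATAAACCATATTGCCGATAAA	(ydcU)	1	0	7	10	0
1644411	16	1644394	+	TAAAGATTTTTTTGTGCATGCCGATAGT	flxA	0	0	280	2	1
1676085	1	1676104	-	TAATATTTTGCGAGTTCACGCCGAAATA	pntA	0	0	140	169	0
1823008	44	1823029	-	AACGTAAATCACCCGAGTTGCCGATAAC	ves	0	0	18	0	0
1840188	1	1840186	+	TAACGTTATTGTCTCTGCTACTGATAAC	ynjH	0	0	29	2	1
1970737	57	1970761	-	TAAAGTTTCCCCCCTCCTTGCCGATAAC	tar-tap-cheRBYZ	0	0	251	0	1
1975314	101	1975347	-	TAAACTTTCCCAGAATCCTGCCGATATT	(flhC)motAB-cheAW	1	0	302	1	1
1979379	2	1979356	+	TGAAATTGCACCAGATCGAGCCGATAAT	(otsA)	1	0	26	27	0
1999845	91	1999853	-	TGCAGAAACGGATAATCATGCCGATAAC	fliAYZ	0	0	1257	15	1
2001692	110	2001721	-	TAAAGGTTGTTTTACGACAGACGATAAC	fliC	0	0	2319	11	1
2001856	43	2001841	+	TAAACTTTGCGCAATTCAGACCGATAAC	fliDST	0	0	633	356	0
2017629	18	2017601	+	TCAAGACGCAGGATAATTAGCCGATAAG	fliLMNOPQR	0	0	989	980	0
2232326	3	2232358	-	TAACAAAACGCTGTAAGCGGCCGATATC	(preT)	1	0	49	47	0
2484776	2	2484747	+	TCAACTTCAACCACAATGGGTCGATATC	(evgS)	1	0	23	33	0
2683494	2	2683512	-	AAAGCGTGAAATGAACATTGCCGATTAT	(glyA)	1	0	375	415	0
2850743	51	2850785	-	TAAAATTATAGGCGTCGGTGCCGATAAC	(hypD)	1	0	6	7	0
2860228	2	2860201	+	TAAGGATCTTGGTCTGGTTGCCGATACA	(ygbJ)ygbK	1	0	13	10	0
3082647	11	3082628	+	TAAAGATGCCGGAAGAGTAGCCGATATG	(speA)	1	0	133	193	0
3101896	3	3101871	+	GGCGCAACGGCAGATTGCTGCCGATAAC	(mutY)yggX	1	0	369	370	0
3217148	21	3217162	-	TAAAGATAACCGCAGCGGGGCCGACATA	aer	0	0	225	12	1
3246148	2	3246175	-	AAAGCGACCAATTAACAGCGCCGATAAA	(yqjA)	1	0	140	130	0
3339939	2	3339902	+	TAAACTTCTGCTGCGCGTAAACGATATT	(kdsD)kdsC	1	0	228	241	0
3524439	9	3524407	+	CAAGTTAAACTCCACGCTTGCCGATAGC	yrfF	0	0	62	53	0
3677244	67	3677273	-	TAAAGTTCTGCCCTTACGCGCCGATAAT	yhjH	0	0	511	2	1
3706702	1	3706643	+	TCCTCTATCACCGACCAAATTCGAAAAG	(proK)	1	1	62	44	0
3844022	11	3844039	-	TAAAAAAGCGATTGGCGCTGCCGATGGT	(uhpT)	1	0	25	1	0
3846459	1	3846440	+	AAAACAGGGTCGCTAACAGGCCGATATC	(uhpC)	1	0	9	8	0
4016533	1	4016575	-	GAGAGTTTTTTCATTGCCTGCCGATAAT	(rmuC)	1	0	60	78	0
4119023	1	4118999	+	TACAGATTTTGTCGATTTCGTCGATAAA	(hslU)	1	0	1085	1337	0
4131349	3	4131304	+	TAAACAGGCGAAGAAATTTGCCGATATG	(metF)	1	0	6	3	0
4162805	3	4162795	+	TGAAGGCGCAGCACGCAGTGACGATAAC	(btuB)	1	0	72	92	0
4228823	6	4228793	+	GAAAGAGTATCTGGTGACGGTCGATAAA	(rluF)	1	0	73	73	0
4327161	19	4327146	+	TAAAGTTCTGGCAGAGCAGGTCGATGAA	(yjdA)yjcZ	1	0	52	1	1
4564123	1	4564096	+	GAATAAACTGCAGATCTTTGCCGATATT	(yjiN)	1	0	17	17	0
4589660	94	4589638	+	TAAAGTTTTTCCTTTCCAGGCCGAAAAT	tsr	0	0	630	9	1
4591362	3	4591380	-	AAAGATTAATCTCCTTATGCCCGATAAC	tsr/yjiZ_convergent	0	0
4621181	1	4621145	+	TACAGCCCCCGCCATCCATGCCGATAAC	(lplA)	1	0	30	31	0
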