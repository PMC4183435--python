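peak_center	fat_flhd	fat_flhc	locus	intragenic	expr_wt	expr_dflhd	expr_dflhc	sig_dflhd	sig_dflhc
395571	3		ampH	0	108	76	87	0	0
395571	3		sbmA	0	37	20	25	0	0
1104400	3		(csgC)ymdABC	1	219	2	3	1	1
1130152	13	16	flgAMN	0	319	3	3	1	1
1130152	13	16	flgBCDEFGHIJ	0	2664	9	11	1	1
1327204	4	5	sohB	0	77	154	147	0	0
1327204	4	5	yciK	0	52	62	51	0	0
1964280	12	17	flhBAE	0	137	0	0	1	1
1986188	28	18	yecR	0	653	2	1	1	1
1999877	15	7	fliAZY	0	1257	1	1	1	1
2011110	20	10	fliE	0	418	2	1	1	1
2011110	20	10	fliFGHIJK	0	719	3	2	1	1
2017573	38	27	fliLMNOPQR	0	509	1	2	1	1
	0	0	fliDST	0	633	3	3	1	1
3576809	2	7	gntR	0	160	140	127	0	0
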