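# Reference pCNV spectrum from the published 10-year two-setting diagnostic
# series.  Locus rows are split by dosage: del / dup count cases carrying only
# that dosage at the locus; del_and_dup counts cases carrying both.  The
# locus_total row is the union of the three.  Blank printed cells mean the
# source table left the cell empty (zero prenatal cases).
# note: "sum_rounded" marks printed aggregate cells that equal the sum of the
# already-rounded sub-rows rather than a direct rounding of count/denominator;
# "half_even" marks exact .5 ties the source rounded down; "typo" marks a cell
# inconsistent with every rounding of the printed counts.
row	locus	dosage	prenatal_count	pediatric_count	pre_adr	pre_rf	ped_adr	ped_rf	note_ped_adr	note_ped_rf	note_pre_rf
22q11.21_total	22q11.21	locus_total	7	57	0.70	26.92	1.74	17.82		sum_rounded	
22q11.21_del	22q11.21	del	4	46	0.40	15.38	1.40	14.38			
22q11.21_dup	22q11.21	dup	3	11	0.30	11.54	0.34	3.44			
15q11-q13_total	15q11-q13	locus_total	1	37	0.10	3.85	1.13	11.57		sum_rounded	
15q11-q13_del	15q11-q13	del	0	31			0.95	9.69			
15q11-q13_dup	15q11-q13	dup	1	6	0.10	3.85	0.18	1.88			
16p11.2_total	16p11.2	locus_total	0	22			0.67	6.88			
16p11.2_del	16p11.2	del	0	15			0.46	4.69			
16p11.2_dup	16p11.2	dup	0	7			0.21	2.19			
Xp22.31_total	Xp22.31	locus_total	0	17			0.52	5.32		sum_rounded	
Xp22.31_del	Xp22.31	del	0	7			0.21	2.19			
Xp22.31_dup	Xp22.31	dup	0	10			0.31	3.13			
1q21_total	1q21	locus_total	0	15			0.46	4.70		sum_rounded	
1q21_del	1q21	del	0	3			0.09	0.94			
1q21_dup	1q21	dup	0	10			0.31	3.13			
1q21_del_and_dup	1q21	del_and_dup	0	2			0.06	0.63			
7q11.23_total	7q11.23	locus_total	0	14			0.42	4.38	sum_rounded		
7q11.23_del	7q11.23	del	0	8			0.24	2.50			
7q11.23_dup	7q11.23	dup	0	6			0.18	1.88			
16p13.11_total	16p13.11	locus_total	3	10	0.30	11.54	0.30	3.13	sum_rounded		
16p13.11_del	16p13.11	del	3	4	0.30	11.54	0.12	1.25			
16p13.11_dup	16p13.11	dup	0	6			0.18	1.88			
17q12_total	17q12	locus_total	0	9			0.27	2.81			
17q12_del	17q12	del	0	5			0.15	1.56			
17q12_dup	17q12	dup	0	4			0.12	1.25			
3q29_total	3q29	locus_total	0	7			0.21	2.19			
3q29_del	3q29	del	0	6			0.18	1.88			
3q29_dup	3q29	dup	0	1			0.03	0.31			
17p12_total	17p12	locus_total	1	7	0.10	3.85	0.21	2.19			
17p12_del	17p12	del	1	2	0.10	3.85	0.06	0.63			
17p12_dup	17p12	dup	0	5			0.15	1.56			
17p13.3_total	17p13.3	locus_total	2	6	0.20	7.69	0.18	1.88			
17p13.3_del	17p13.3	del	1	4	0.10	3.85	0.12	1.25			
17p13.3_dup	17p13.3	dup	1	2	0.10	3.85	0.06	0.63			
8p23.1_total	8p23.1	locus_total	0	5			0.15	1.56			
8p23.1_del	8p23.1	del	0	4			0.12	1.25			
8p23.1_dup	8p23.1	dup	0	1			0.03	0.31			
5q35_total	5q35	locus_total	0	5			0.15	1.56			
5q35_del	5q35	del	0	5			0.15	1.56			
15q13_total	15q13	locus_total	2	4	0.20	7.69	0.12	1.25			
15q13_del	15q13	del	1	1	0.10	3.85	0.03	0.31			
15q13_dup	15q13	dup	1	3	0.10	3.85	0.09	0.94			
2q13_total	2q13	locus_total	0	3			0.09	0.93		sum_rounded	
2q13_del	2q13	del	0	1			0.03	0.31			
2q13_dup	2q13	dup	0	1			0.03	0.31			
2q13_del_and_dup	2q13	del_and_dup	0	1			0.03	0.31			
17p11.2_total	17p11.2	locus_total	0	3			0.09	0.94			
17p11.2_del	17p11.2	del	0	2			0.06	0.63			
17p11.2_dup	17p11.2	dup	0	1			0.03	0.31			
7q35-q36_total	7q35-q36	locus_total	0	3			0.09	0.94			
7q35-q36_del	7q35-q36	del	0	3			0.09	0.94			
17q21.31_total	17q21.31	locus_total	0	2			0.06	0.62		sum_rounded	
17q21.31_del	17q21.31	del	0	1			0.03	0.31			
17q21.31_dup	17q21.31	dup	0	1			0.03	0.31			
17q11.2_total	17q11.2	locus_total	0	2			0.06	0.62		half_even	
17q11.2_del	17q11.2	del	0	2			0.06	0.62		half_even	
22q13.33_total	22q13.33	locus_total	0	2			0.06	0.62		half_even	
22q13.33_del	22q13.33	del	0	2			0.06	0.62		half_even	
4q35_total	4q35	locus_total	0	1			0.03	0.31			
4q35_del	4q35	del	0	1			0.03	0.31			
Xq28_total	Xq28	locus_total	1	1	0.10	3.85	0.03	0.31			
Xq28_dup	Xq28	dup	1	1	0.10	3.85	0.03	0.31			
recurrent_total	_aggregate	recurrent_total	17	232	1.69	65.38	7.08	72.50			
subtelomeric	_sporadic	subtelomeric	5	35	0.50	19.23	1.07	10.94			
interstitial	_sporadic	interstitial	4	53	0.40	15.38	1.62	16.56			
sporadic_total	_aggregate	sporadic_total	9	88	0.90	36.42	2.69	27.50			typo
all_pcnv	_aggregate	all_pcnv	26	320	2.59	100.00	9.77	100.00			
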