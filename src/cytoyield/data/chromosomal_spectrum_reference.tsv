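# Reference chromosomal-abnormality spectrum from the published 10-year
# two-setting diagnostic series (case counts and the ADR/RF percentages as
# printed).  kind: leaf rows carry single-category case counts; subtotal and
# total rows aggregate the leaves listed in the builder's layout.
row	label	kind	prenatal_count	pediatric_count	pre_adr	pre_rf	ped_adr	ped_rf
xxy	47,XXY	leaf	8	27	0.22	1.50	0.61	7.63
xyy	47,XYY	leaf	2	5	0.06	0.37	0.11	1.41
monosomy_x	45,X	leaf	47	24	1.30	8.80	0.54	6.78
xxx	47,XXX	leaf	7	7	0.19	1.31	0.16	1.98
sca_subtotal	Sex chromosome aneuploidy	subtotal	64	63	1.77	11.99	1.42	17.80
trisomy21	Trisomy 21	leaf	227	150	6.29	42.51	3.38	42.37
trisomy18	Trisomy 18	leaf	82	10	2.27	15.36	0.23	2.82
trisomy13	Trisomy 13	leaf	22	3	0.61	4.12	0.07	0.85
other_autosomal_aneuploidy	Other aneuploidy	leaf	49	2	1.36	9.18	0.05	0.56
autosomal_subtotal	Autosomal aneuploidy	subtotal	380	165	10.53	71.16	3.71	46.61
polyploidy	Triploid & tetraploid	leaf	26	0	0.72	4.87		
numerical_total	Numerical abnormality	total	470	228	13.03	88.01	5.13	64.41
robertsonian_balanced	Robertsonian translocations	leaf	6	4	0.17	1.12	0.09	1.13
other_balanced	Other balanced	leaf	27	24	0.75	5.06	0.54	6.78
balanced_subtotal	Balanced rearrangements	subtotal	33	28	0.91	6.18	0.63	7.91
unbalanced_rearrangement	Unbalanced rearrangements	leaf	31	98	0.86	5.81	2.21	27.68
structural_total	Structural abnormality	total	64	126	1.77	11.99	2.84	35.59
all_chromosomal	All chromosomal abnormalities	grand_total	534	354	14.80	100.00	7.97	100.00
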