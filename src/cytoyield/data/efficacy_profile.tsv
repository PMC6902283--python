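# Layout and replication profile for the diagnostic-efficacy table.
#  source            : how the detected 10-year case count is derived from a
#                      classified cohort (leaf:<category>, locus_del:<locus>,
#                      aggregate:<key>, sum:<row>+<row>).
#  exp_dp            : decimal places used when rendering the expected
#                      per-10,000-newborn column.
#  det_dp_pre/ped    : decimal places used when rendering the detected
#                      per-10,000-newborn column in each setting (the source
#                      table's per-row precisions).
#  expected_override : expected-per-10k value used in replication mode where
#                      the source table's aggregate rounding is not a direct
#                      rounding of 10,000/N.
#  det_override_ped  : detected 10-year case-count override in replication mode
#                      (pws_as: the published detected figure implies 17
#                      pediatric cases, fewer than the 31 deletions tabulated
#                      at 15q11-q13).
#  det_render_override_pre : rendered detected-per-10k override (prenatal
#                      45,X: the source rounds 2.35 down to 2.3 while rounding
#                      1.35 and 0.35 up elsewhere).
row	label	incidence_label	source	exp_dp	det_dp_pre	det_dp_ped	expected_override	det_override_ped	det_render_override_pre
trisomy21	Trisomy 21	trisomy21	leaf:trisomy21	0	0	1
monosomy_x	45,X	monosomy_x	leaf:monosomy_X	1	1	1			2.3
xxy	47,XXY	xxy	leaf:XXY	0	1	1
xxx	47,XXX	xxx	leaf:XXX	0	1	1
xyy	47,XYY	xyy	leaf:XYY	0	1	1
robertsonian_balanced	Balanced Rob.	robertsonian_balanced	leaf:robertsonian_balanced	0	1	1
all_chromosomal	All chromosome abnormalities	all_chromosomal	aggregate:all_chromosomal	0	0	0	64
dgs_vcfs	DGS/VCFS	dgs_vcfs	locus_del:22q11.21	1	1	1
16p11.2_del	16p11.2 del	16p11.2_del	locus_del:16p11.2	1	1	2
1q21.1_del	1q21.1 del	1q21.1_del	locus_del:1q21	1	1	2
pws_as	PWS/AS	pws_as	locus_del:15q11-q13	2	1	2		17
wbs	WBS	wbs	locus_del:7q11.23	0	1	1
recurrent_genomic_disorders	All recurrent genomic disorders	recurrent_genomic_disorders	aggregate:recurrent	0	2	1	25
all_pcnv	All pCNVs	all_pcnv	aggregate:all_pcnv	0	1	0	33
total_cytogenomic	Total cytogenomic abnormalities	total_cytogenomic	sum:all_chromosomal+all_pcnv	0	1	0	97
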