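# Epidemiological inputs, on the percent scale.
#  context=calibration_aneuploidy : live-birth incidences of the four
#    aneuploidies used to calibrate the incidence-vs-ADR regression.
#  context=calibration_syndrome   : reported population prevalences of the five
#    deletion syndromes used to calibrate the prevalence-vs-ADR regression;
#    ranges use "lo-hi" syntax.
#  context=efficacy               : newborn incidences (1-in-N) used by the
#    diagnostic-efficacy table.
label	context	value_percent	one_in_n
trisomy21	calibration_aneuploidy	0.12	830
monosomy_x	calibration_aneuploidy	0.025	4000
trisomy18	calibration_aneuploidy	0.0133	7500
trisomy13	calibration_aneuploidy	0.0044	22700
dgs_vcfs	calibration_syndrome	0.05-0.0625
wbs	calibration_syndrome	0.005-0.013
pws_as	calibration_syndrome	0.011-0.014
sms	calibration_syndrome	0.004-0.006
hnpp	calibration_syndrome	0.016
trisomy21	efficacy		830
monosomy_x	efficacy		4000
xxy	efficacy		1000
xxx	efficacy		900
xyy	efficacy		1000
robertsonian_balanced	efficacy		1100
all_chromosomal	efficacy		154
dgs_vcfs	efficacy		4000
16p11.2_del	efficacy		5800
1q21.1_del	efficacy		7400
pws_as	efficacy		8000
wbs	efficacy		10000
recurrent_genomic_disorders	efficacy		396
all_pcnv	efficacy		291
total_cytogenomic	efficacy		100
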