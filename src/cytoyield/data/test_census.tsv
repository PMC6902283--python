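# Test-combination census of the reference 10-year cohort: how many cases in
# each setting received each combination of karyotyping (K), aCGH (A) and
# FISH (F).  FISH-only rows are split by panel purpose.
setting	tests	fish_purpose	count
prenatal	karyotype	none	2269
prenatal	karyotype|acgh	none	781
prenatal	karyotype|fish	aneuploidy_panel	331
prenatal	karyotype|acgh|fish	aneuploidy_panel	185
prenatal	acgh	none	31
prenatal	acgh|fish	aneuploidy_panel	7
prenatal	fish	aneuploidy_panel	4
pediatric	acgh	none	1526
pediatric	karyotype|acgh	none	1401
pediatric	karyotype	none	1091
pediatric	karyotype|fish|acgh	aneuploidy_panel	194
pediatric	karyotype|fish	aneuploidy_panel	133
pediatric	acgh|fish	aneuploidy_panel	89
pediatric	fish	aneuploidy_panel	9
pediatric	fish	targeted_microdeletion	66
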