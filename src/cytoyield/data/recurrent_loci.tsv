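# Default recurrent genomic-disorder loci, GRCh37, 1-based closed intervals.
# Boundaries are cytoband-anchored configuration defaults chosen to cover the
# common low-copy-repeat-flanked critical regions; edit to match a local
# reporting convention.  Columns are tab-separated.
locus	chromosome	start	end	deletion_syndrome	duplication_syndrome
22q11.21	22	18900000	21500000	DiGeorge/velocardiofacial syndrome	22q11.2 duplication syndrome
15q11-q13	15	22800000	28400000	Prader-Willi/Angelman syndrome	15q11-q13 duplication syndrome
16p11.2	16	29600000	30200000	16p11.2 deletion syndrome	16p11.2 duplication syndrome
Xp22.31	X	6450000	8140000	X-linked ichthyosis (STS deletion)	Xp22.31 duplication
1q21	1	146500000	147900000	1q21.1 deletion syndrome	1q21.1 duplication syndrome
7q11.23	7	72700000	74100000	Williams-Beuren syndrome	7q11.23 duplication syndrome
16p13.11	16	15500000	16300000	16p13.11 microdeletion	16p13.11 microduplication
17q12	17	34800000	36200000	17q12 deletion syndrome	17q12 duplication syndrome
3q29	3	195700000	197350000	3q29 deletion syndrome	3q29 duplication syndrome
17p12	17	14100000	15500000	Hereditary neuropathy with liability to pressure palsies	Charcot-Marie-Tooth disease type 1A
17p13.3	17	1000	2500000	Miller-Dieker syndrome	17p13.3 duplication syndrome
8p23.1	8	8100000	11800000	8p23.1 deletion syndrome	8p23.1 duplication syndrome
5q35	5	175600000	176900000	Sotos syndrome	5q35 duplication
15q13	15	30900000	32400000	15q13.3 microdeletion	15q13.3 microduplication
2q13	2	110850000	110980000	2q13 (NPHP1) deletion	2q13 duplication
17p11.2	17	16700000	20200000	Smith-Magenis syndrome	Potocki-Lupski syndrome
7q35-q36	7	145800000	148800000	7q35-q36 deletion	7q35-q36 duplication
17q21.31	17	43700000	44200000	Koolen-de Vries syndrome	17q21.31 duplication
17q11.2	17	29100000	30300000	NF1 microdeletion	17q11.2 duplication
22q13.33	22	51100000	51250000	Phelan-McDermid syndrome	22q13.33 duplication
4q35	4	190100000	191000000	4q35 deletion	4q35 duplication
Xq28	X	153200000	153600000	Xq28 deletion	MECP2 duplication syndrome
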