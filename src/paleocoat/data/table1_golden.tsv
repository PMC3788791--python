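section	key	value
phenotype	CH734	Black
phenotype	CH735	Yellow (wild type)
phenotype	CH716	?
phenotype	CH717	?
phenotype	CH1075	Black
phenotype	CH1076	?
phenotype	CH756	?
phenotype	CH1047	?
phenotype	CH773	?
phenotype	CH768	?
phenotype	CH770	?
phenotype	CH771	Black
phenotype	CH1042	Yellow (wild type)
phenotype	CH767	Black
phenotype	CH708	Yellow (wild type)
phenotype	CH709	Yellow (wild type)
phenotype	CH710	?
phenotype	CH711	Yellow (wild type)
phenotype	CH712	Yellow (wild type)
phenotype	CH1119	?
phenotype	CH1120	Black
phenotype	CH1122	?
phenotype	CH1244	?
summary	n_samples	23
summary	mc1r_determined	15
summary	cbd103_determined	19
summary	both_loci_determined	11
summary	r301c_carriers	9
summary	r301c_homozygous	5
summary	r301c_heterozygous	4
summary	black_total	5
summary	black_dog_morphotype	4
summary	black_wolf_morphotype	1
summary	agouti_wild_type	6
summary	recessive_yellow	0
summary	phenotype_undetermined	12
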