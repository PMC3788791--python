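name	gene	variant_kind	variant_start	variant_length	ref_allele	alt_allele	ref_label	alt_label	ref_alias	alt_alias
MC1R_R301C	MC1R	snp	30	1	C	T	C	T
MC1R_R306ter	MC1R	snp	45	1	C	T	C	T	E	e
CBD103_DG23	CBD103	deletion	24	3	GGG		GGG	-	K^y	K^B
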