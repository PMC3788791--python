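sample_id	morphotype	site	site_no	dating	mc1r_r301c	mc1r_r306ter	cbd103_k
CH734	dog	Bury	14	4451-4247	C/C	C/C	-/-
CH735	dog	Bury	14	4451-4247	C/C	C/C	GGG/GGG
CH716	dog	Luka Vrubiletskaia	13	4950-4650	ND	ND	GGG/GGG
CH717	dog	Soloncheny	12	4950-4650	ND	ND	GGG/GGG
CH1075	wolf	Ulug Depe	11	5450-3950	C/C	C/C	GGG/-
CH1076	dog	Ulug Depe	11	5450-3950	ND	ND	GGG/GGG
CH756	dog	Saint Paul Trois Chateaux	10	5900-5600	ND	ND	GGG/GGG
CH1047	dog	Twann	9	6150-5400	C/C	C/C	ND
CH773	dog	Bordusani	8	6798-5900	ND	ND	GGG/GGG
CH768	dog	Harsova	7	6500-5900	ND	ND	GGG/GGG
CH770	dog	Harsova	7	6500-5900	T/T	C/C	ND
CH771	dog	Harsova	7	6500-5900	C/T	C/C	-/-
CH1042	dog	Herxheim	6	7030-6960	C/C	C/C	GGG/GGG
CH767	dog	Isaccea	5	7440-7318	T/T	C/C	GGG/-
CH708	dog	Pad'Kalashnikova	4	10233-9909	C/T	C/C	GGG/GGG
CH709	dog	Pad'Kalashnikova	4	10233-9909	C/T	C/C	GGG/GGG
CH710	dog	Ust'belaya	3	10233-9909	ND	ND	GGG/GGG
CH711	dog	Ust'belaya	3	10233-9909	C/T	C/C	GGG/GGG
CH712	dog	Ust'belaya	3	10233-9909	T/T	C/C	GGG/GGG
CH1119	dog	Icoana	2	10876-7960	ND	ND	GGG/GGG
CH1120	dog	Icoana	2	10876-7960	T/T	C/C	-/-
CH1122	dog	Icoana	2	10876-7960	T/T	C/C	ND
CH1244	wolf	Torgashinskaya cave	1	15000-12000	C/C	C/C	ND
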