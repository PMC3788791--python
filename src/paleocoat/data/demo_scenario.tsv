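sample_id	mc1r_r301c	mc1r_r306ter	cbd103_k
SIM01	C/C	C/C	-/-
SIM02	C/C	C/C	GGG/GGG
SIM03	C/T	C/C	GGG/-
SIM04	T/T	C/C	GGG/GGG
SIM05	C/T	C/C	-/-
SIM06	C/C	C/C	GGG/GGG
SIM07	T/T	C/C	GGG/-
SIM08	C/C	C/T	GGG/GGG
SIM09	C/C	T/T	GGG/-
SIM10	C/T	C/C	GGG/GGG
SIM11	C/C	C/C	GGG/-
SIM12	T/T	C/C	GGG/GGG
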