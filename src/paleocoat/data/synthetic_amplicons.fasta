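>MC1R synthetic 79 nt Mc1r amplicon stand-in (carries R301C and R306ter sites)
CTGACCATCCTGCTGGGCATCTTCAGCCTGCGCTACGAGCACATTCGGACCTTGGCAGTT
GTTCCTGACAGCTACATGA
>CBD103 synthetic 76 nt CBD103 amplicon stand-in (carries the deltaG23 window)
AAGCTTTCCGGCACGTTCTGCCTAGGGTCAGACCTGCAATGTCACCTTCCAGGATGCTGG
TTCCAAGTGCTTGCAA
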