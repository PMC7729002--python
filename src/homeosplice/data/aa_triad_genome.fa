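>chr2A
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCGCGCGTTCGGGATGTCCCCTTTCTCGGCCTTCTCGGCTT
TCGCTGCCTCCTGTGGTGCCTCCCCTTCCGCTCTTCGGGTGCGGGCCGCCCTCTTCTAACTTGTTCCCGG
CTTCCCTTCCGCTGTGCGTCCTTCCTGTCTCCCGCCTCCTGTCGCCCTGGGGCCGGGCCTGGCTCCCCTT
GTGGGGGTCGGGTTCCGGTTCTTGCTGTGCCCCGCGTGCTGCGGCTGTCTTTGTTGTGGTGGCCTCTGCG
CTTAACCCCCCCCTTCTGTCGGTGGTTTGCCTTTCCCGGGTCCCTGCTTTCTTCTCCGGTCTTCTGGTTG
GCTTCCGTCCCGTTCCTGCGGTGCCTTTTTTTGGGTTTCCGGGGCTCTTGGGATGTCGCGGGGTGCTGTC
TCGGGTCGGGCTGGTTGTTTCCTCGGTCCTTGTTCGTGCGTGGTGTCGTTCGTGCGGCTCTCGTGTGGTC
CTCCGCTTGCCTTCTTCTAACCGGCTCCGCCGCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
>chr2B
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCTGTTGGCCGGGCATGGCTGTCTCGGTGGTGGTGTCGTCGC
TTCCGGTGGTGGTGTTCCTCCGGGTCTGTGTGCTTTCCTCGGCCCCTCCTGGTGTCTAACGTTTTGCTCT
TGGCGGTTTGCCCTCGTGTTGGTGCTTCCCCCGCCCCTTGTTCTTCCGCGTTGGTTTCTCTGTGTGCTGC
GTGGCTGTTCGGTCCCTGCCCTTTGTGTCCTGCTCTCGGTCCGCCTCTTCTTTCCGCTCCGGTGTAACTG
TGCTGCTCGCGTGTTTGCCTTGCGTGGCGGTCCCGGCTGCCGGCTTCCCTTCCGCCGGTTGCCGCTTCCC
TCTCCATGTCCGGCTCCCTTGGTTCCGTCGGTTCGGGCTGTTCGCTCCTTTGCGTGCCGTCGCGGGGTCT
TCCGCGGTCGGGCGGCCTCGCTGCCTCCGGCTGTCTCGCTTAACCGGCTGCCGTCCCCCCCCCCCCCCCC
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
CCCCCCCCCCCCCCC
>chr2D
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCTGCTCCCTCCGTATGGCCTGTGCTGGCGTGTCGGGTCCGG
TGCCGCCTCTCGCTTTCGGTTCCGTCCCGTTCGCCGTGTGCTGTTCCCCGCCTTGCTAACGTGTGTTTGT
CGCTCCGCGTCTGGCTGCGCTGGCTCCGTCCCTTTCGCTCGCGCCGGTCTCGCGGCCCGCTTTCCCTGCC
CTTTCGCCTCCCGGTCGTCGCTTCTCGCTCCTGGCCCGTAACTCCGGTCGTTTTCTGGCGTGTTCGTCGC
GTCCCTGCCGTGGGTCTCCTCTTTCTGGTTGTCCCCCTCGTTCCGGGGGTTGCCCTCGCTCATGGCTTCG
TGTTCCTCGTCGGTCGGCCGGGCCGGTCGGTCCGGTGCTGGTTCGTTCTCCCCGGGTCGGGCCCCTGGCT
CGTCGCTTCTCTGCCTTTGTCCGTCCTAACCTTCGCCGTGCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC
C
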