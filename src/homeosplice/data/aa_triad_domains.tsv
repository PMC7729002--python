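gene_id	domain	start_codon	end_codon
TaHSP90AA-2A	HATPase_c	16	36
TaHSP90AA-2A	HSP90	41	61
TaHSP90AA-2B	HATPase_c	16	36
TaHSP90AA-2B	HSP90	41	61
TaHSP90AA-2D	HATPase_c	16	36
TaHSP90AA-2D	HSP90	41	61
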