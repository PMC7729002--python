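gene	gene_id	subfamily	subgenome	chromosome_group	exon_number	isoform_number
TaHSP90AA-2A	TraesCS2A01G033700	AA	A	2	3	5
TaHSP90AA-2B	TraesCS2B01G047400	AA	B	2	3	6
TaHSP90AA-2D	TraesCS2D01G033200	AA	D	2	3	8
TaHSP90AB-7A	TraesCS7A01G242200	AB	A	7	3	10
TaHSP90AB-7B	TraesCS7B01G149200	AB	B	7	3	13
TaHSP90AB-7D	TraesCS7D01G241100	AB	D	7	3	6
TaHSP90AB-5A	TraesCS5A01G260600	AB	A	5	3	6
TaHSP90AB-5B	TraesCS5B01G258900	AB	B	5	3	9
TaHSP90AB-5D	TraesCS5D01G268000	AB	D	5	3	7
TaHSP90B-7A	TraesCS7A01G529900	B	A	7	15	7
TaHSP90B-7B	TraesCS7B01G446900	B	B	7	15	13
TaHSP90B-7D	TraesCS7D01G517800	B	D	7	15	7
TaHSP90C1-5A	TraesCS5A01G251000	C1	A	5	19	2
TaHSP90C1-5B	TraesCS5B01G249000	C1	B	5	19	4
TaHSP90C1-5D	TraesCS5D01G258900	C1	D	5	19	2
TaHSP90C2-5A	TraesCS5A01G101900	C2	A	5	20	5
TaHSP90C2-5B	TraesCS5B01G106300	C2	B	5	20	9
TaHSP90C2-5D	TraesCS5D01G113700	C2	D	5	20	7
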