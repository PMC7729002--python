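chr2A	homeosplice	gene	101	592	.	+	.	gene_id "TaHSP90AA-2A"; subgenome "A"; subfamily "AA"; triad_id "AA-2";
chr2A	homeosplice	transcript	101	592	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.1";
chr2A	homeosplice	exon	101	196	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.1";
chr2A	homeosplice	exon	317	352	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.1";
chr2A	homeosplice	exon	473	592	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.1";
chr2A	homeosplice	transcript	101	592	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.nimi";
chr2A	homeosplice	exon	101	190	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.nimi";
chr2A	homeosplice	exon	323	352	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.nimi";
chr2A	homeosplice	exon	473	592	.	+	.	gene_id "TaHSP90AA-2A"; transcript_id "TaHSP90AA-2A.nimi";
chr2B	homeosplice	gene	101	545	.	+	.	gene_id "TaHSP90AA-2B"; subgenome "B"; subfamily "AA"; triad_id "AA-2";
chr2B	homeosplice	transcript	101	545	.	+	.	gene_id "TaHSP90AA-2B"; transcript_id "TaHSP90AA-2B.1";
chr2B	homeosplice	exon	101	196	.	+	.	gene_id "TaHSP90AA-2B"; transcript_id "TaHSP90AA-2B.1";
chr2B	homeosplice	exon	309	344	.	+	.	gene_id "TaHSP90AA-2B"; transcript_id "TaHSP90AA-2B.1";
chr2B	homeosplice	exon	426	545	.	+	.	gene_id "TaHSP90AA-2B"; transcript_id "TaHSP90AA-2B.1";
chr2B	homeosplice	transcript	101	545	.	+	.	gene_id "TaHSP90AA-2B"; transcript_id "TaHSP90AA-2B.nimi";
chr2B	homeosplice	exon	101	344	.	+	.	gene_id "TaHSP90AA-2B"; transcript_id "TaHSP90AA-2B.nimi";
chr2B	homeosplice	exon	426	545	.	+	.	gene_id "TaHSP90AA-2B"; transcript_id "TaHSP90AA-2B.nimi";
chr2D	homeosplice	gene	101	531	.	+	.	gene_id "TaHSP90AA-2D"; subgenome "D"; subfamily "AA"; triad_id "AA-2";
chr2D	homeosplice	transcript	101	531	.	+	.	gene_id "TaHSP90AA-2D"; transcript_id "TaHSP90AA-2D.1";
chr2D	homeosplice	exon	101	196	.	+	.	gene_id "TaHSP90AA-2D"; transcript_id "TaHSP90AA-2D.1";
chr2D	homeosplice	exon	283	318	.	+	.	gene_id "TaHSP90AA-2D"; transcript_id "TaHSP90AA-2D.1";
chr2D	homeosplice	exon	412	531	.	+	.	gene_id "TaHSP90AA-2D"; transcript_id "TaHSP90AA-2D.1";
chr2D	homeosplice	transcript	101	531	.	+	.	gene_id "TaHSP90AA-2D"; transcript_id "TaHSP90AA-2D.nimi";
chr2D	homeosplice	exon	101	196	.	+	.	gene_id "TaHSP90AA-2D"; transcript_id "TaHSP90AA-2D.nimi";
chr2D	homeosplice	exon	412	531	.	+	.	gene_id "TaHSP90AA-2D"; transcript_id "TaHSP90AA-2D.nimi";
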