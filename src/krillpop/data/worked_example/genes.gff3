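##gff-version 3
chr1	krillpop	gene	11	70	.	+	.	ID=geneA
chr1	krillpop	exon	11	40	.	+	.	ID=geneA.exon1;Parent=geneA
chr1	krillpop	exon	53	70	.	+	.	ID=geneA.exon2;Parent=geneA
chr1	krillpop	CDS	17	40	.	+	.	ID=geneA.cds1;Parent=geneA
chr1	krillpop	CDS	53	64	.	+	.	ID=geneA.cds2;Parent=geneA
chr1	krillpop	five_prime_UTR	11	16	.	+	.	ID=geneA.u5_1;Parent=geneA
chr1	krillpop	three_prime_UTR	65	70	.	+	.	ID=geneA.u3_1;Parent=geneA
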