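##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=100>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	p1_1	p1_2	p2_1	p2_2
chr1	5	.	A	T	.	PASS	.	GT	1|0	0|0	0|0	0|0
chr1	20	.	C	G	.	PASS	.	GT	1|1	1|1	0|0	0|0
chr1	30	.	G	A	.	PASS	.	GT	1|0	1|0	1|0	1|0
chr1	55	.	T	C	.	PASS	.	GT	0|0	0|0	1|1	0|0
chr1	80	.	A	G	.	PASS	.	GT	1|1	0|0	1|1	1|1
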