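##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AB,Number=1,Type=Float,Description="Allele balance">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	sample00000	sample00001	sample00002	sample00003	sample00004	sample00005
1	1000	v0	A	G	.	PASS	.	GT:DP:GQ:AB	0/1:30:60:0.500	0/1:30:60:0.500	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	1500	v1	C	T	.	PASS	.	GT:DP:GQ:AB	0/1:30:60:0.500	0/1:30:60:0.500	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	2000	v2	G	A	.	PASS	.	GT:DP:GQ:AB	0/1:30:60:0.500	0/1:30:60:0.500	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	2500	v3	T	C	.	PASS	.	GT:DP:GQ:AB	0/1:30:60:0.500	0/1:30:60:0.500	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	3000	v4	A	G	.	PASS	.	GT:DP:GQ:AB	0/1:5:60:0.500	0/0:5:60:0.000	0/0:5:60:0.000	0/0:5:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	3500	v5	C	T	.	PASS	.	GT:DP:GQ:AB	0/1:5:60:0.500	0/0:5:60:0.000	0/0:5:60:0.000	0/0:5:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	4000	v6	G	A	.	PASS	.	GT:DP:GQ:AB	0/1:5:60:0.500	0/0:5:60:0.000	0/0:5:60:0.000	0/0:5:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	4500	v7	AT	A	.	PASS	.	GT:DP:GQ:AB	0/1:30:60:0.900	0/1:30:60:0.500	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	5000	v8	C	T	.	PASS	.	GT:DP:GQ:AB	0/1:30:60:0.900	0/1:30:60:0.500	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000	0/0:30:60:0.000
1	5500	v9	G	A	.	PASS	.	GT:DP:GQ:AB	./.:30:60:0.000	./.:30:60:0.000	./.:30:60:0.000	./.:30:60:0.000	0/1:30:60:0.500	0/0:30:60:0.000
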