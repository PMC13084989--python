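##fileformat=VCFv4.2
##source=whalepop-toy-fixture
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth across samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##contig=<ID=sc1,length=2000000>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	s1	s2	s3	s4
sc1	100	.	A	T	.	PASS	MQ=60;DP=160	GT:DP:GQ	0|1:40:90	0|0:40:90	0|1:40:90	1|1:40:90
sc1	200	.	C	G	.	PASS	MQ=60;DP=160	GT:DP:GQ	0|0:40:90	0|1:40:90	0|0:40:90	0|1:40:90
sc1	300	.	G	A	.	PASS	MQ=20;DP=160	GT:DP:GQ	0|1:40:90	0|1:40:90	0|0:40:90	0|0:40:90
sc1	400	.	T	C	.	PASS	MQ=25;DP=160	GT:DP:GQ	1|1:40:90	0|1:40:90	0|0:40:90	0|1:40:90
sc1	500	.	A	G	.	PASS	MQ=60;DP=160	GT:DP:GQ	0|1:40:10	0|0:40:10	0|1:40:90	0|0:40:90
sc1	600	.	C	T	.	PASS	MQ=60;DP=400	GT:DP:GQ	0|1:100:90	1|1:100:90	0|0:100:90	0|1:100:90
sc1	700	.	G	C	.	PASS	MQ=60;DP=160	GT:DP:GQ	0|0:40:90	0|1:40:90	1|1:40:90	0|1:40:90
sc1	800	.	T	A	.	PASS	MQ=60;DP=160	GT:DP:GQ	0|1:40:90	0|0:40:90	0|1:40:90	0|0:40:90
sc1	900	.	A	C	.	PASS	MQ=60;DP=160	GT:DP:GQ	1|1:40:90	0|1:40:90	0|1:40:90	0|0:40:90
sc1	1000	.	C	G	.	PASS	MQ=60;DP=160	GT:DP:GQ	0|0:40:90	0|1:40:90	0|0:40:90	0|1:40:90
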