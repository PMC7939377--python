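name	chrom	start	end	ref_structure	pop_structure	fwd_primer	rev_primer	H	PIC	pic_class	private_population
Xgma1	1	3295349	3295385	GCG (12)	GCG (4)	TCGGTCGTGCCGGGAAGGGGGACTGGAGGGTAGGGTCTGG	CCCAACCGCAACAGACCAAACCCAGCCGCAACCGCAGAGC	.	.	.	margaritiferum
Xgma2	1	9033349	9033373	GCC (8)	GCC (10)	GGTCGAGGGCTCCTCTCTCTCTACCGTCCCCGCTCGATCC	GGCAGCGCGACGATAGGCGCGAGTTGGACTGGCGGAGAGC	.	.	.	margaritiferum
Xgma3	1	78120648	78120675	ACT (9)	ACT (6)	ATACATACATATCTGTTAGGCCATGCATGAACATCTAAAC	GAAACCGGAAGAAAGATTGCACTCGATCGTGTAATAGTCG	.	.	.	margaritiferum
Xgma4	8	1256427	1256444	CCACGC (3)	CCACGC (2)	GCCCAGCAGACCAGCCGCGTTGGCTGGCGGGACGGAGCAG	CAGTAGACCGTCGGGACGGCGCCGCTGGGCCTCGGCTTGG	.	.	.	margaritiferum
Xgma5	9	48460761	48460787	GGATG (5)	GGATG (4)	TGTGGGATTTCGCTTCTCGAGGGAACGGAATTACGGGAAG	GCCAAATCAAAGCTAGACTCGACGCTAGTGCCATGTGACG	.	.	.	margaritiferum
Xgma6	10	4107816	4107841	GAG (8)	GAG (5)	GCCGGTGGTGGAGCGGTTGCGGCGGCGGCAGGGCACGGCC	CCACCCACTTGCCCCACTTGCGCATCCGAACGCCGCGATA	.	.	.	margaritiferum
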