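# Genetic variation of the candidate genes that harboured SNPs: number of SNPs,
# phased haplotypes, haplotype-pair genotypes, and per-site nucleotide diversity
# (pi, multiplied by 1000) in the native (JH) and semiarid (QG) sites.
gene_id	n_snp	n_haplotype	n_genotype	pi_jh_x1000	pi_qg_x1000
MluLR17106	1	2	3	0.412	0.200
MluLR2876	5	11	21	0.618	0.480
MluLR16886	4	12	15	0.509	0.500
MluLR7126	4	12	18	0.349	0.406
MluLR5294	3	5	9	0.525	0.611
MluLR12213	7	34	53	1.656	1.667
MluLR12611	7	21	26	1.693	1.727
MluLR13061	3	5	8	0.788	0.712
MluLR17624	5	15	28	1.269	1.113
MluLR16034	5	9	21	1.392	1.185
MluLR4945	5	14	26	0.747	0.932
MluLR15146	6	11	15	0.776	0.940
MluLR4148	17	75	71	2.526	2.385
MluLR18082	3	6	8	0.885	0.574
MluLR18372	5	12	23	2.157	1.488
MluLR3563	3	4	5	0.304	0.316
MluLR14116	4	8	13	0.333	0.407
MluLR18370	3	6	10	0.523	0.538
MluLR9412	2	4	4	1.650	1.697
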