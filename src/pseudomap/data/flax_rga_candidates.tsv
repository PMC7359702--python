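qtl_no	qtl_id	chrom	qtl_start	qtl_end	gene_id	gene_pos	rga_class
12	QPM-crc-LG1	1	16920407	18739647	Lus10026756	17134471	RLK
12	QPM-crc-LG1	1	16920407	18739647	Lus10026761	17159664	RLK
12	QPM-crc-LG1	1	16920407	18739647	Lus10026765	17189168	NBS
12	QPM-crc-LG1	1	16920407	18739647	Lus10009703	18125241	RLK
13	QPM-crc-LG7	7	3817603	3817863	Lus10023437	3725947	TM-CC
14	QPM-crc-LG9	9	357191	357510	Lus10001677	429431	RLK
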