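name	gene	forward	reverse	product_bp	annealing_c	gc_f_printed	gc_r_printed	source	flags	alt_forward
MollCOI154	COI	TGGGGGTTTTGGTAATTGGT	TCAACCAGTACCAGCTCCA	154	57	45.00	52.63	this_panel
MollCOI253	COI	GGAGTAGGAACTGGTTGGAC	CAGCTGCTAACACAGGCA	253	57	55.00	55.56	this_panel
MollCOI255	COI	TGGAGCTGGTACTGGTTGA	GCCCCAGCTAAAACAGGTAT	255	57	52.63	50.00	this_panel
Moll12S100	12S	TTGTATACCGTCGTCGTCAG	AGCTGCACCTTGATCTGAC	100	57	50.00	52.63	this_panel
Moll12S150	12S	TATGCTTGCCGGGCAACT	ACGGCCATACACCAACTGA	150	59	55.56	52.63	this_panel
Moll12S195	12S	GTATTGCCGTTGTCAGCTT	CCTTACTCCTAAGTTCACCTTC	195	56	47.37	45.45	this_panel
Moll16S	16S	GTCCTGTGAATGGTTTGACGAG	TTGCTGCCCCAGCCAAAAC	228	60	50.00	57.89	this_panel
COI204	COI	TGTTACAGCTCACGCATTTGTT	CCGGTACCTGCACCTCTTTC	204	60	40.91	60.00	published
Sepi	COI	CACCAGACATAGCCTTCC	GCCAGCATGAGATAGATTAC	155	54	55.56	45.00	published
NADH	NADH	TCGAGCCATAGCTCAAACCA	GCGAGTGGTAGTGAAAGAGT	147	59	50.00	50.00	published
NZMS	Cytb	TGTTTCAAGTGTGCTGGTTT	CAAATGGGCTAGTTGATTCTTT	92	56	40.00	36.36	published
16SrRNA	16S	TGAGCGTGCTAAGGTAGC	AGCCAACATCGAGGTCGC	360	60	55.56	61.11	published
unionoida	16S	GCTGTTATCCCCGGGGTAR	AAGACGAAAAGACCCCGC	170	58	61.11	55.56	published	ambiguous_forward	GCTGTTATCCCCGGGGTA
veneroida	16S	CSCTGTTATCCCYRCGGTA	TTDTAAAAGCCGAGAAGACCC	159	56	52.63	42.86	published
Ceph18S	18S	CGCGGCGCTACATATTAGAC	GCACTTAACCGACCGTCGAC	173-235	61	55.00	60.00	published
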