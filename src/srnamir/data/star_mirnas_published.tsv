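family	mature_seq	ml	c_reads	t_reads	total_reads	fold_change
nta-miR171*	TGATGTTGGAATGGCTCAATC	21	224.6	506.4	731	+2.25
nta-miR396*	GTTCAAGAAAGCTGTGGGAAA	21	151.2	155.3	306.5	+1.03
nta-miR162*	GGAGGCAGCGGTTCATCGATC	21	54	67.5	121.5	+1.25
nta-miR166a*	GGAATGTTGTCTGGCTCGAGG	21	2533.5	15091.3	17624.8	+5.95
nta-miR393a*	ATCATGCTATCCCTTTGGA	19	71.3	258.8	330.1	+3.59
nta-miR393b*	ATCATGTTATCCCTTTGGA	19	30.2	81	111.2	+2.63
nta-miR393c*	ATCATGCTATCCCTTTGG	18	19.4	227.3	246.7	+11.19
nta-miR172*	GCAGCATCTTCAAGATTCACA	21	49.7	36	85.7	-1.37
nta-miR167d*	AGGTCATCTAGCAGCTTCAAT	21	153.3	337.6	490.9	+2.19
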