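family	mature_seq	ml	c_reads	t_reads	total_reads	fold_change
nta-miR168a	TCGCTTGGTGCAGGTCGGGAC	21	10142.6	7722.3	17864.9	-1.31
nta-miR168b	TCGCTTGGTGCAGGTCGGGAT	21	30.2	38.3	68.5	+1.26
nta-miR168c	TCGCTTGGTGCAGGTCGGGACC	22	8.6	15.8	24.4	+1.75
nta-miR167a	TGAAGCTGCCAGCATGATCTA	21	11987.1	6536.2	18523.3	-1.83
nta-miR167b	TATCTGATTGGCGTGGCAAAT	21	7678.2	4404.7	12082.9	-1.74
nta-miR4367a	ACGCAGGAGGGATGATACT	19	169	391.6	560.1	+2.32
nta-miR4367b	TACGCAGGAGAGATGATGCTG	21	725.7	342.1	1067.8	-2.12
nta-miR394a	TTGGCATTCTGTCCACCTCC	20	216	78.8	294.8	-2.72
nta-miR160a	GCGTGCGAGGAGCCAAGCATA	21	1051.8	3241.1	4292.9	+3.08
nta-miR160b	GCGTATGAGGAGCCAAGCATA	21	2816.4	6011.8	8828.2	+2.13
nta-miR160c	CGTATGAGGAGCCAAGCATA	20	6.5	27	33.5	+3.73
nta-miR160d	TGCCTGGCTCCCTGTATGCCA	21	41	27	68	-1.5
nta-miR390a	AAGCTCAGGAGGGATAGCACC	21	665.2	709	1374.2	+1.07
nta-miR390b	AAGCTCAGGAGGGATAGCGCC	21	149	247.6	396.6	+1.66
nta-miR390c	AGCTATGTTGCTCGGACTCTC	21	19.4	18	37.4	-1.07
nta-miR156a	TTGACAGAAGATAGAGAGCAC	21	127864.8	30725	158589.8	-4.16
nta-miR156b	TGACAGAAGAGAGTGAGCACC	21	207.3	83.3	290.6	-2.47
nta-miR156c	TGACAGAAGAGAATGAGCAC	20	7756	2349.8	10105.8	-3.3
nta-miR156d	TTGACAGAAGAGAGAGAGCAC	21	34.6	13.5	48.1	-2.46
nta-miR156e	TTGATAGAAGATAGAGAGCAC	21	54	22.5	76.5	-2.34
nta-miR156f	AGTGACAGAAGAGAGTGAGCA	21	23.8	0	23.8	-23.8
nta-miR397a	TCATCTGCGCTGCACTCAATCA	22	19.4	29.3	48.7	+1.49
nta-miR397b	ATTGAGTGCAGCGTTGATGAA	21	295.9	87.8	383.7	-3.34
nta-miR162a	TCGATAAACCTCTGCATCCAG	21	1043.2	650.5	1693.7	-1.6
nta-miR396a	TTCCACAGCTTTCTTGAA	18	127.4	308.4	435.8	+2.41
nta-miR396b	TTAGAGGAAGGAGAAGTT	18	6.5	27	33.5	+3.73
nta-miR396c	AAGCTGTGGGAAAATATGGCA	21	1056.2	515.4	1571.6	-2.05
nta-miR172a	AGAATCATGATGATGCTGCAT	21	95	56.3	151.3	-1.68
nta-miR172b	GGGAATCTTGATGATGCTGCA	21	103.7	171.1	274.8	+1.64
nta-miR172c	AGAATCTTGATGATGCTGCAT	21	11941.8	6464.2	18406	-1.85
nta-miR172d	GGAATCTTGATGATGCTGCAT	21	455.7	234.1	689.8	-1.94
nta-miR172e	TGAATCTTGATGATGCTGCAT	21	8546.5	4098.6	12645.1	-2.08
nta-miR171a	TGATTGAGCCGTGCCAATATC	21	172.8	191.3	364.1	+1.11
nta-miR171b	TGATTGAGCCGCGTCAATATC	21	6.5	27	33.5	+3.73
nta-miR171c	TTGAGCCGCGCCAATATCACT	21	84.2	49.5	133.7	-1.69
nta-miR171d	TGAGCCGGACCAATATCACT	20	47.5	4179.6	4227.1	+86.2
nta-miR171e	CGATGTTGGTGAGGTTCAATC	21	36.7	60.8	97.5	+1.64
nta-miR171f	ATTGATGCGACTCAATCTGAA	21	62.6	13.5	76.1	-4.39
nta-miR166a	TTCGGACCAGGCTTCATTCCC	21	490.3	360.1	850.4	-1.36
nta-miR166b	TCTCGGACCAGGCTTCATTCC	21	993.5	783.3	1776.8	-1.27
nta-miR166c	TTGAGGGGAATGTTGTCTGGC	21	17.3	4.5	21.8	-3.33
nta-miR166d	AATGAAGACTGATCCAAGATC	21	1274.3	1811.9	3086.2	+1.42
nta-miR827	TTAGATGAACATCAACAAACA	21	190.1	85.5	275.6	-2.21
nta-miR2111	TAATCTGCATCCTGAGGTTTA	21	4.3	20.3	24.6	+4.02
nta-miR159	TTTGGATTGAAGGGAGCTCTA	21	1665.2	472.7	2137.9	-3.52
nta-miR164a	TGGAGAAGCAGGGCACGTGCA	21	18816.5	9453.2	28269.7	-1.99
nta-miR164b	CATGTGCCTGTCTTCCCCATC	21	25.9	33.8	59.7	+1.29
nta-miR479	CGTGATATTTGTTTGGCTCATC	22	32.4	195.8	228.2	+5.89
nta-miR477a	ACTCTCCCTCAAGGGCTTCT	20	84.2	141.8	226	+1.68
nta-miR477b	TGTCTCTCCCTCAAGGGCTTC	21	116.6	24.8	141.4	-4.56
nta-miR1444	ACATTCCGGCAATCTTCTCC	20	25.9	13.5	39.4	-1.86
nta-miR319	TGGGAGCCGTAAGATTGAG	19	17.3	13.5	30.8	-1.26
nta-miR1446	TGAACTCTCTCCCTCAATGGCT	22	7170.7	7443.2	14613.9	+1.04
nta-miR395a	CTGAACTCGGTGTAACAAATC	21	8.6	18	26.6	+1.98
nta-miR395b	ATACCTGGCGCTATACATTAA	21	21.6	2.3	23.9	-6.85
nta-miR398	GAATTGTAAGAACATGTAAAA	21	142.5	488.4	630.9	+3.41
nta-miR1384a	AGGAGAATGACAAACCTGACA	21	451.4	630.2	1081.6	+1.4
nta-miR1384b	AGGAGAATCACAAACCTGACA	21	17.3	51.8	69.1	+2.89
nta-miR132a	ATTGTTACATGTAGCACTGGC	21	97.2	49.5	146.7	-1.94
nta-miR132b	ATTGTTACATGTAGCACTGGA	21	157.7	119.3	277	-1.32
nta-miR132c	ATTGTTACATGTAACACTGGC	21	79.9	56.3	136.2	-1.41
nta-miR132d	TATTGTTATATGTTGCACTGGC	22	190.1	128.3	318.4	-1.48
nta-miR3627a	TGTCGCTGGAGAGATGGCACTT	22	1101.5	8658.6	9760.1	+7.85
nta-miR3627b	TCGCAGGAGAGATGGCACTTGC	22	200.9	213.8	414.7	+1.06
nta-miR169a	TGGCAAGCATCTTTGGCGACT	21	47.5	47.3	94.8	+1
nta-miR169b	AACTTGAAGGGTCGTGTA	18	6.5	18	24.5	+2.53
nta-miR4275	ATAAGTGTTCATTGGACAAA	20	34.6	31.5	66.1	-1.1
nta-miR3	GTGTTCATGTTATAATTC	18	6.5	15.8	22.3	+2.24
nta-miR1477	ATGGATAGAAATGAAGGGAGA	21	19.4	11.3	30.7	-1.66
nta-miR399a	GGGCTACTTTCTATTGGCATG	21	15.1	90	105.1	+5.65
nta-miR399b	GGGTAGCTCTCCGTTTGGCAGA	22	79.9	69.8	149.7	-1.14
nta-miR399c	GGGTTACTCTTTATTGGCATG	21	51.8	101.3	153.1	+1.94
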