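>nta-miR168a
TCGCTTGGTGCAGGTCGGGAC
>nta-miR168b
TCGCTTGGTGCAGGTCGGGAT
>nta-miR168c
TCGCTTGGTGCAGGTCGGGACC
>nta-miR167a
TGAAGCTGCCAGCATGATCTA
>nta-miR167b
TATCTGATTGGCGTGGCAAAT
>nta-miR4367a
ACGCAGGAGGGATGATACT
>nta-miR4367b
TACGCAGGAGAGATGATGCTG
>nta-miR394a
TTGGCATTCTGTCCACCTCC
>nta-miR160a
GCGTGCGAGGAGCCAAGCATA
>nta-miR160b
GCGTATGAGGAGCCAAGCATA
>nta-miR160c
CGTATGAGGAGCCAAGCATA
>nta-miR160d
TGCCTGGCTCCCTGTATGCCA
>nta-miR390a
AAGCTCAGGAGGGATAGCACC
>nta-miR390b
AAGCTCAGGAGGGATAGCGCC
>nta-miR390c
AGCTATGTTGCTCGGACTCTC
>nta-miR156a
TTGACAGAAGATAGAGAGCAC
>nta-miR156b
TGACAGAAGAGAGTGAGCACC
>nta-miR156c
TGACAGAAGAGAATGAGCAC
>nta-miR156d
TTGACAGAAGAGAGAGAGCAC
>nta-miR156e
TTGATAGAAGATAGAGAGCAC
>nta-miR156f
AGTGACAGAAGAGAGTGAGCA
>nta-miR397a
TCATCTGCGCTGCACTCAATCA
>nta-miR397b
ATTGAGTGCAGCGTTGATGAA
>nta-miR162a
TCGATAAACCTCTGCATCCAG
>nta-miR396a
TTCCACAGCTTTCTTGAA
>nta-miR396b
TTAGAGGAAGGAGAAGTT
>nta-miR396c
AAGCTGTGGGAAAATATGGCA
>nta-miR172a
AGAATCATGATGATGCTGCAT
>nta-miR172b
GGGAATCTTGATGATGCTGCA
>nta-miR172c
AGAATCTTGATGATGCTGCAT
>nta-miR172d
GGAATCTTGATGATGCTGCAT
>nta-miR172e
TGAATCTTGATGATGCTGCAT
>nta-miR171a
TGATTGAGCCGTGCCAATATC
>nta-miR171b
TGATTGAGCCGCGTCAATATC
>nta-miR171c
TTGAGCCGCGCCAATATCACT
>nta-miR171d
TGAGCCGGACCAATATCACT
>nta-miR171e
CGATGTTGGTGAGGTTCAATC
>nta-miR171f
ATTGATGCGACTCAATCTGAA
>nta-miR166a
TTCGGACCAGGCTTCATTCCC
>nta-miR166b
TCTCGGACCAGGCTTCATTCC
>nta-miR166c
TTGAGGGGAATGTTGTCTGGC
>nta-miR166d
AATGAAGACTGATCCAAGATC
>nta-miR827
TTAGATGAACATCAACAAACA
>nta-miR2111
TAATCTGCATCCTGAGGTTTA
>nta-miR159
TTTGGATTGAAGGGAGCTCTA
>nta-miR164a
TGGAGAAGCAGGGCACGTGCA
>nta-miR164b
CATGTGCCTGTCTTCCCCATC
>nta-miR479
CGTGATATTTGTTTGGCTCATC
>nta-miR477a
ACTCTCCCTCAAGGGCTTCT
>nta-miR477b
TGTCTCTCCCTCAAGGGCTTC
>nta-miR1444
ACATTCCGGCAATCTTCTCC
>nta-miR319
TGGGAGCCGTAAGATTGAG
>nta-miR1446
TGAACTCTCTCCCTCAATGGCT
>nta-miR395a
CTGAACTCGGTGTAACAAATC
>nta-miR395b
ATACCTGGCGCTATACATTAA
>nta-miR398
GAATTGTAAGAACATGTAAAA
>nta-miR1384a
AGGAGAATGACAAACCTGACA
>nta-miR1384b
AGGAGAATCACAAACCTGACA
>nta-miR132a
ATTGTTACATGTAGCACTGGC
>nta-miR132b
ATTGTTACATGTAGCACTGGA
>nta-miR132c
ATTGTTACATGTAACACTGGC
>nta-miR132d
TATTGTTATATGTTGCACTGGC
>nta-miR3627a
TGTCGCTGGAGAGATGGCACTT
>nta-miR3627b
TCGCAGGAGAGATGGCACTTGC
>nta-miR169a
TGGCAAGCATCTTTGGCGACT
>nta-miR169b
AACTTGAAGGGTCGTGTA
>nta-miR4275
ATAAGTGTTCATTGGACAAA
>nta-miR3
GTGTTCATGTTATAATTC
>nta-miR1477
ATGGATAGAAATGAAGGGAGA
>nta-miR399a
GGGCTACTTTCTATTGGCATG
>nta-miR399b
GGGTAGCTCTCCGTTTGGCAGA
>nta-miR399c
GGGTTACTCTTTATTGGCATG
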