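>TRBV1
ATTAGCGATTAGGCTCTCACGGATATCATGGATCAGTCTTGCCGTTGTGCACAATGCCACACT
>TRBV2
AAGATAAGCCCGCAATAAAGCGCAACTTAACCATGACGATGAAGCCGTAAAGGCTGCTTGCCT
>TRBV3-1
ATAACGCTAGAACTGGAGCAAGTCATTGCCGCAACTATGGGGGAGATACTTAAGTGTGAATAT
>TRBV3-2
TTCTCAGCGCGGCTCCGTAAGGAGATCTTTCATTTTCGCCGCACCAATGAACCTTGCTGCCTT
>TRBV4-1
ATTGTGTCCATAAGTGTTTGGGATGTTCACCAGATAGTATTGGTCAATCTTACGTGCTCCCGG
>TRBV4-2
GGAAGTCCGGGCCTAAAAGTATATAAATCTATCAATTACGCTTTTCGATCTCAATGCCCGAAT
>TRBV4-3
TGCAGTCTATGTCCTGACCTTTACATAGAGCGAGGATCCTCTAGGCGGACACTTTGTTGCTCT
>TRBV5-1
CACGGATACGCCTCGAGGTACTCAGACCAAACTGTTTGATAATAGTGATCCCGATGTATGTAA
>TRBV5-3
GAAGAAGTTCATTACCGGCCTGGAAGGCTGCATTTTTGCCTTGAATCTGATCTATGTCAACGT
>TRBV5-4
TCTGAGTTCAGTAGGACGGAAGGCGTGCCGTACAGCAGGAGGTTTCCATTCAGATGTGTAGGT
>TRBV5-5
ACGCTACCAAGGTCCAGGCGCCTCATCACTCTAACGACATCACGTCACGTTATCTGCTGATCC
>TRBV5-6
CGGCATGCAGCGTTTTAATATGACACACCAGCAGCTGGGGTCTCATCAGTCCCGTGTTTCATG
>TRBV5-7
CCTATGTGGTCAAAGGAGTTTTTCAGTGGGCACATTTCTGCGGTTGTGCATGTCTGTGACTTG
>TRBV5-8
TGTGCGCAGCTCCTGGCTCGGAGTAGTAAGGAACACGGCTACAGTTGATACTTTTGTGTCAGT
>TRBV6-1
TCGATTTATGTGGCTAGGTAGTAATAAAAAGAGTGAGTATGGAAATACACTCGCTGCACAATG
>TRBV6-2
TGGAGACGCTCCGTCTCCACGTTTTGAAGTATAGCTTCGGCTCCGGATAGGCAATGCAAGTGA
>TRBV6-3
GGACTCCTTGGAACAAGTTGTTGTTCCACACTCCCGCTTGTGTCTGGGGCGGTATGCTTTACC
>TRBV6-4
TTGTCAATAAGTCACCCTCATGATCGGCGTCTCTTACACCTGGAGCCCCCAGGCTGCGCACTA
>TRBV6-5
TGAAATAATGTAAGGTGCGACCTAATAGGCCCGCGGTTATTCCCTCCTGTTGACTGCGTACGG
>TRBV6-6
TTCTTCACTTGACCGGTCATCTTTGGCGTGCCTTGATCGCACGCGTTGTGCCAGTGCCAGTTA
>TRBV6-7
AGAGAACAACGTATCGAGGAGTCACGGTACGAAAAGGAAGGGACATTTAGTTATTGCCATGTC
>TRBV6-8
CGCGAGGAACAGCGGGGAAGCAATCTGGGCGATGCCAAATATGGCGGCGGACCCTGTAGTCTC
>TRBV7-1
ACGACCACAATTATGTCGCGCACTGTCGCGAAACAAACGTGGGTTGAAGATATGTGTGAGCCT
>TRBV7-2
ACTGCCTAGCTACACCATAGCAAGAATTAGCAGGGGACTTGCTTAGATACGGCGTGCAAGACC
>TRBV7-3
CGTATTGCCGGTTACGGCTATAAGATTAGCTTATAATAGGACCTCGCGTAGGTCTGCACTGAT
>TRBV7-4
CGCCTTTCCAAAGCATGCAGTGTGTTGGGGATGCCGTTTATCGTCTGAACGCTATGTAGGTCA
>TRBV7-6
GAACCGTGCGACTGTAGATCACGGGCAATCCTGATATAGGCAGGCTAAGCGTAATGTGGGCTT
>TRBV7-7
GCGCGTCCCGAATGGCAGCTTCGGAGACGCGCTCCCCCGAGTGACTCGTTGCGATGTGCCCAC
>TRBV7-8
TCCCGCATAGCGCGCTGGTTTCTCTGGGTGATGACCCCAGTCCACTCCACGGTATGTGGGCTA
>TRBV7-9
TACCCGGGTAGTTTGAGGAGTCCCCAAGAGTTATCGGAAGCTGTTTGACTAATTTGCGCTACA
>TRBV9
GTGAGCATGACCCCATTCCGAGGCCCATCGTAAACAGCTCTGTCAGACGAGCTATGCTACCCA
>TRBV10-1
TATGTAGTAGTGACGGAAGGATTACACGGCTACAAAAGCACTAATCTATGCGACTGCGCCTTG
>TRBV10-2
TTCACAGAAATGTCCTGTATGGTACAATACAGCAGTAGAATAATGCAATATCCTTGTTATAGC
>TRBV10-3
GCTATGATGACTCACATTAAAACCGGGCTGTTTTGCGTCGTAAACGCACTGTCGTGTACGCGT
>TRBV11-1
GGGTTCACGCAGCAAACCACTACGCGTTAATAAGACAGGGGGCTTCTAGGTATATGCGAGGCT
>TRBV11-2
TGCGTCTTGCTCCTATGGATCCAGTGTGGTGGTCCAGTCCTTCTCGACTAAGAATGTACAGGC
>TRBV11-3
AATATCTGCGGTGTGCTCGCGCACTTCCTGAATACTTGGCAATCCTCAGTCTTTTGCTTCCGT
>TRBV12-1
AGCTTCTCGGCGTTTACGGATTTCACCGACCTTTCAGTGGAAAAGATCATTCTCTGCGACACA
>TRBV12-2
TCTAAACTCGACGCGGGGCCCCTGCACCCCATCGCACCTTCAGCTACTCCAGGATGTCCCTAT
>TRBV12-3
GATCTTTGCTTGAGCCTTATAACCACATACGGGTTGTATATTTAAAGTGTATTCTGCGTGCGG
>TRBV12-4
AAAGAGAGGGGCGCAACGTACGCCCTTTATCTCCCGTCAGTTCTTAAGCAAGAGTGCGCGTCC
>TRBV13
AAGGAACTGCGGCTTTACTTATTGTTCACTTCAATAACTTAGCTGGTTACCTCCTGCTAGATC
>TRBV14
GACTGAGTGTGAGTCTATCTACATGAACTGTTTCACGGCTGCTCCATCAGCGAATGCCCACAA
>TRBV15
GAACGGATATGATTCTATGTCGAACTCTAGACGGTTTATTCGATTGTTTTACACTGTGCGATA
>TRBV16
CAACGCTACGGGAGGGTATGTAATCAGGCTAATCGTTGATGGGGTTAATTGATTTGTGGGCGG
>TRBV17
CGAAACATAGACCACGACTTCAATTAGAGATGGCGTCATATACCCTCACATAGCTGTTTCCGA
>TRBV18
AAGCGTTCGCCAACCCCTGGACTTGTCCATGCAAGGAGTTATTACCAGCGGCGTTGTGAGTAG
>TRBV19
TAGCAAGAGATGAAATTTGATGATGCGCGGACTATTTCGGACGTGGCCACTATGTGTTTTGGT
>TRBV20-1
AGTGATTTGGTGTTTTAGACATTTCTGTTTTGGAACTCATGCTTAGTCCTATATTGTCTCCTC
>TRBV21-1
CCGGTGTACGGGACCTGAGAATTGCCCGGTAGCAAAGTACAGATCAATCTGAGATGTACCCTG
>TRBV23-1
TGACACTGGTCAGCGGGGCATCCGATACTTTTGTGCATCCATCTGGATAGGGACTGTGGCCAG
>TRBV24-1
TGGTTTACAAGAACTGTGAAGCTGATGTGGCTGGGTTACTAGAGTTGAAAGGGGTGCCAGCCA
>TRBV25-1
TTATGTAATCTGATCTACAGAGTGCAGGTAAATAGATATGATTCTCGCTGACGATGTAGACTT
>TRBV26
GGACGGCATGGCCTCCGAAAGTCAGAATTTCCTACATTATTGAGAATTCCAGGTTGTTCCGGG
>TRBV27
ACTGCTTGTACGTACAAAACCTCGAGGAAAGTATGTAATGGCGAGGCGCAGTACTGCTTGGTC
>TRBV28
AAGTCGTAACAGCACTCGCAGTTCTCATAGCGGTATTATGCTGCAGGTATAATATGTATTTGA
>TRBV29-1
CTCGAGGGGCCGCGTAGTGCTCTACTGATTTCGGCGCCATCATGTAGCCCCCGTTGTTCCAAG
>TRBV30
CAGACTCGAAAGTGGGTAAAGACAATAGAATTGATACTTTCTTAATCGTCGCGATGTACCGTG
>TRBD1
GGGACAGGGGGC
>TRBD2
GGGACTAGCGGGGGGG
>TRBJ1-1
TCCGATATATTCCATTGTTGTGACCGGCGGGGGGAGCCTTGTACTTCT
>TRBJ1-2
CCATTGACTTTCCTCGCGCGATCATGTCTTAAGTGGAATCTTTGGGTA
>TRBJ1-3
AAATACCCATTTCGCATACGAACGATACAACTAGGTTCTTTCTATTCC
>TRBJ1-4
GACCTAACGTTTATTGTGCGCCACAACACCCGGTCATAGTATGGCCCA
>TRBJ1-5
CGGCTGGATTTCTCCGGAATCTTAGGACGCGTGTTATTTTTCCTCTTT
>TRBJ1-6
ATTACAACGTTCCCACAGTGTCGAGATTGGCTACTAATGTATCTCGTC
>TRBJ2-1
TCAGCCAAATTCATAAGGGGAGGGTGGTTCGCTGTTAGATGGGTACTA
>TRBJ2-2
ACGTATGGGTTCTATGCCCATTCATAGAGGGTAACACACGCAAAGTGA
>TRBJ2-3
GTCCTTATATTCTGTAGCATTGGGACCCCTAGAAACGATGTGGTGAAG
>TRBJ2-4
GAGCATCACTTCGGCGTCCATCGAGGGGATTTCGTGAACCTTCGTCCA
>TRBJ2-5
GTTAGTAGTTTCAGTCACGTCTCCTGTACTATGCCCCCTACTGTTACA
>TRBJ2-6
GGGCATTAGTTCTATCGATTCCATATAGCGACTATCCGATGTGTTTGT
>TRBJ2-7
ACTCCCGGCTTCTTTGTAATGTATGAACCCAGTAAATCATTTGAACAT
>TRBJ2-2p
GGCTGGGGTTTTCCATGTCGCCCGCATCTGCACAAGCAAGATACCATG
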