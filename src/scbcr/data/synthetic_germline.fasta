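>IGHD1-26*01
TGGCTCATCGATA
>IGHD2-2*03
TAGGTGTTGTGT
>IGHD2-8*01
ATTACCCGGGAGCTC
>IGHD3-10*01
ACGTATCGGGAA
>IGHD6-6*01
CGCGCGGCGCTAGTC
>IGHJ3*02
CTATGACATGGGGCCAAGGCAGGTGGCCTAGT
>IGHJ4*02
TAGGGTTGGGGCCAAGGCCCGCATAGGTCT
>IGHJ5*01
TCTGACCTGGGGCCAAGGCGACTGTGCAGGA
>IGHJ6*01
TCAACTGGGCTGGGGCCAAGGCGATCGTAGAGAA
>IGHV1-18*01
TTGAGCACTGGCTCTACTCTGAGGTACTCGTTGTTTTTATGTGTCACTAAGTTGTGGGGTTCATCAGCTATCCTATCAACAAGTAACCCAGAAATGCACAGAAGAGCGGGCACGGGCAGAGTGCATTTGACTGCACCTCCCTGTGCGAGA
>IGHV1-18*02
TTGAGCACTGGCTCTACTCTGAGGTACTCGTTGTTTTTATGTGTCACTAAGTTGTGGGGTTCATCAGCAATCCTATCAACAAGTAACCCAGAAATTCACAGAAGAGCGGGCACGGGCAGAGTGCATTTGACTGCACCTCCCTGTGCGAGA
>IGHV1-18*04
TTGAGCACTGGCTCTACTCTGAGTTACTCGTTGTTTTTATGTGTCACTAAATTGTGGGGTTCATCAGCTATCCTATCAACAAGTAACCCAGAAATGCACAGAAGAGCGGGCACGGGCAGAGTGCATTTGACTGCACCTCCCTGTGCGAGA
>IGHV1-2*01
GCTGGCTTTACCGCTCTCACAGACCTCTCGGGATGTGTCCACAGTGTCTTCTACCGCCCCGGCTTAAAGGAAACAGCGCTACCGCGTATACTCGATCCGAGATGTGAGTTTATGTTGAATAAGGGCCAACACAGCGTTGTCTGTGCGAGG
>IGHV3-23*01
AAGGAGGGCTTTTTGAGAACGCTGACAGCCAAAGATCGACCAGTGAGAATTGCCACAAGGTGTTTAATGCATTCCGGGATGCTTTCAAACGGGGTCTCTTCCGACGTTATCCTCGGATCGTACTACCTCTCGAGCACGGCGTGTGCGAAA
>IGHV4-34*01
GTACGGATACCAGATCGTTACCAACAATTATGCGATTCGCTAAGAGTTTACGCTACCCGGGTAGCTCATGGGGCCGCGGTGCCAGGATTAGAGCCTACGAATAATTCGGAAACAACTGAAACAACCAACACCGCCTGCATCTGTGCGAGG
>IGHV4-39*01
TTTAATGTTATGAGGCCGTGGTATATTCGGTTACTTAGCGGTTTCGATACGAGGACACGGAAGCGACGAGCCCAGCTAAGGTCGACTAACGGGGTCTACGTTTTGTCAACTCGCCACCTGCGGGCAACTCGCCTAATCCTATGTGCGAGA
>IGHV5-51*01
CGTCGGAATTTGACCAAGCGAATTCGAGGGGGCGCCGAGAGTGCGCCTACCTCCCGATGGTTTGTAACGAGAACTTTGCGTCTACGTAGCTCAATGTACAGTACGACGGATGCGGGTATAGGACGGGAACGGACGCAGAGGTGTGCGAGA
>IGKJ1*01
TAATGCTTCGGCCAAGGGGACAATTCGTGT
>IGKJ2*01
GTTGTATGTTCGGCCAAGGGTTTATGCTAGCA
>IGKJ4*01
CAGTTGGTTCGGCCAAGGGGGACACTTGTGG
>IGKV1-5*01
CAATATATCACTCGGCTTTTTCCCGATAACCGGGCTATGTATCAAGAATTCGTAGTACCTAACATCTGCTCTCGGAGTTCCGGTTGCTGGTCGCCATCGAATACCCCTTCGTGCTTAATCGTATTAGGGGTCACAGTGGAGTGTCAACAG
>IGKV2-28*01
GTCTGTCAATACGCTGGTGTAATGGGATTCATGGTAACCATCATGATGCGATGTGTCCGGGATGGCCCGTACTACCCAGGGGGCATTGCCCCGGGCCGACACCTGTCAGCAATCCCAGCGACCGCTTATCCTCTTAGACCGTGTATGCAA
>IGKV3-20*01
AGGTACAATGCACCGGACAGCCTGTCCTGTGAAGGGGTCGCTAGCGTTCGTGATTGTGGCATCTCGTTGATTCGGTTCGAACCGCGCAGTTTTCAATACCACAACTTGACCCCAAAAAAGATTCGGCTGTTATGTAAGGAATGTCAGCAG
>IGKV4-1*01
CAAGAGAACGAGTCTTGGCGAACTAGCAGCCTGAAACGGCGCCCGCTGTGCACGGCACCTGGAGGTCGAAGTTGCAGTAGACCGGATCCCGCCAAGCAGAAGGAACTTGTCGTTTGTGTATCTGTTCTAGTTCAAGGGCCCTGTCAGCAA
>IGLJ1*01
TAACGATTCGGCGGAGGGCCACTCAAGGAA
>IGLJ2*01
TGGTGAATTTCGGCGGAGGGTACGAATCACGA
>IGLJ3*01
GGAGACGTTCGGCGGAGGGGGGTTGACATTG
>IGLJ3*02
CGAGTCGTTCGGCGGAGGGGGGTTGACATTG
>IGLV1-40*01
AGGGTGTGCGGTCTTGGAGCCTCTTGTACTATGCTCGACAGCTGTGTCCGAAGACGTCCCGCCGGTACCCATGCCGTTTGCCCAACATGTTTTAATCTTTCGGGTAAGCTGACTACAACCCGTGAAACCGCTCATGCGAAATGTCAGTCC
>IGLV1-40*02
AGTGTGTGCGGTCTTGGAGCCTCTTGTACTATGCTCGACAGCTGTGTCCGAAGACGTCCCGCCGGTACTCATGCCGTTTGCCCAACATGTTTTAATCTTTCGGGTAAGCTGACTACAACCCGTGAAACCGCTCATGCGAAATGTCAGTCC
>IGLV1-44*01
CCATATAGATATCAGTGTAACGATTCTCTACCACTCCAAGAAAAGCTAAAGAACAACTTTGAGGCACCCCCTTCAACGACGCGTAGCTCAGATCATAGTCTCAGTGTCTCGGTTCAGACTGGTGCGCCGTACAGCATGTTTTGTGCTGCA
>IGLV2-11*01
GCTGCGAAACAGGTGTCTACTCTAAAGACGAAAAGGCCCGGAAGCGAAACCAAAGGGCGTCGTCGCTCCGCGGGAGATCTAGAAGCGCCGTCAACAAAAACTGTCATGCATCCTTTAGGATTCAGTGAGGGAAATGTTAGCTGTAGCTCA
>IGLV3-1*01
AATGGCGTGGATGGCAGAGGTACAGTGGAGCTCTATTGTCATGCTTGGCCTTTTTATATGGTCGGTGGCCTCCCGATACCACTTATTATCAAAAGACGGAGAAAAGCATCCCATTATAGTCTTCGCTCCTACGCCGGAAAATGTCAGGCG
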