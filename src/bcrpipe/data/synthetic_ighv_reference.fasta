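>IGHV1-18*01
AGGTGGATGTGGAAGGCTCACCACGATATCAGCCCGGGAGCGAATTGGGACCCGCGGATGCATTGCTGCGTGGGACGCTGCACGTTATTTATGTTCGGATGCAAGGTTCATTGGGGTCCCATGTTCAGCCCGGAGCCTTGGATGGCCCATTATATGCTTGCGTGTATAGGGTGGAGGTTTTGTTGCTTCATTTTTGCAATGGCTACGCCAGTCGCTGGACCACGGCCAGCCGAGAGAGGCGAGCCCATAGTAACCAACCCTGTGTATGCTAATATGTGGACCAGCCCATGGGTTTGC
>IGHV1-2*01
GTCGATATGAGCGAACAAACATGCTATACCGCCCCTGTTACAGGGCCATATGATATGTTCGCTGTGTGTTCGCTAGCCTTCGAAGTGCAAGCTTTCCTGGGCTTTAAAAAATGGCGCCAAGAAATGAGGGCGAAATTGAAACGTGACCAAAGAAAGAACATGATACAGCTGTTCGGCGCTTCTGATTCGCAAGACCGAAATTGGGGTATAATTTGGGGCAACTGGAACAAAAAAGAAAAGATGTTAGGCATGGGCCTATGGAAGCGCGTTAGCTCGCAGCCTTGGTATAATCAGTGC
>IGHV1-46*01
TTTATCAAGCAGTGTCAACATTGTCCCAGAGGTGGTAAAAAGGATACCTGGCAGGTTGCTCTATGTTGTGTATCAATGATCTCTGATACCCAAGAGCCCTGGTGGGTCCGATGGATACCAACGGAACAGACAGTTTACGATTACATGAAGGCATTTCGTGATAGTAAGAATAAGGCGTGTGCGTTTTTCGAAATAGATATGATGATGGTGCAGAGCCTGCTGTCCCACGAGTATAGATGCTGCGGTCCAAAACACAAAATTGTGAACGAAATGTGGTCGAATCCTTGTTGCCAATGC
>IGHV1-69*01
CCAACGAATTGCATTCGTGATGCTCTCTCCGTGCTGAAAAAGATGATGGACGAGCAAGGACGCTGTTGTTGGTTCTCTCAAACTACATGTATTAATGAGCAATTCATCACTTGGGTAATCCTACGGGTGGTAATGGAACAAACCATACCAAGTTATCGTCTAAAACCACATGCTTGGTGGTACCCTGATGAGGCACCTTGCCATAATGTCCAACCGGACTTTCAAGTTATGCGCTGGGATGGGGTTAATGCATGCCAACGACGCTGGTTTATGAGTTATACCGGTTGGGTACTTTGT
>IGHV2-26*01
CATACGGCGCAAGCTCACTCTGAATCTAACCATCACGAATCGAACAATCATACACAAAGGATGGTATGCCGACCTAAGGAGCGCAGTAGGAGAATGGTCTGGTGGTGTATATGGACTACGGAGGATACTCCCATGGGTTGTCGACAGATGTGCACTGCAGGCCAAAAACATATATGGTCCTACTGGTATGAGGTTACAGGGTATGCTGTTTGTAAAGACCGACAGCTCTATGATCACTACGGGTGTGACGTCATCATGGACTATCACCTGCATAACGTCCTCCCGTATTCAGCCTGT
>IGHV2-5*01
CGTCCGAACGGCTCAAAAAAGAGGATATTGGGCTCTTCTGTGTGGGAACATAGTAATTTCGACAAGTGCGCTACTTCTTTTGAATGCTACCATGGAACAATTTGGGCTATCGATTGGCCAGTGAATTACGAGTTCCTTACCGACCAACCTTGGCATCCGGTCGCTAAAGAGGGCTGTTCATGTGTGCCCCTAGTAGAGTGGAAGAAGATGTTTTACATCTTTTGGGACCGGCGCATGGACAACTTCTGGGTTATCGACTCTTACTGTGTTATTATGATAGGATCCAGGTTCAACTGC
>IGHV2-70*01
GATTATTGCGAGATGCATCGATGCCTTGAAACAAATTGTGCCGACTCAGACCCGCAGACCGGATGTTGTTTGTCAATTGTGTGGGGCGAATGGCCGAAAAATCCATTTGACTGGAGTCCTTTTGGGTCCTGGGAAGACAAACACAGACGAGGTCAAGACCGAGATTGGCGAAAATACTATAATAAAGAGTACCAAAACGCTCAGCAGTGGGTGATGCAATTTAGTTTCTTTAAATTTATGAAATACAAACCTATCATTGTACATGTTGAGGTGCAGGAGAGTAAAATAATGGACTGC
>IGHV3-15*01
ATGACGGGTGACGGACAGGTTGAAAAACTCCACTTTCACATAACATTTTGGAAGGTTCATCAGCACTGCAACTTCATAAAATATACGGGGCATATGTGCCCTATACAGCGGTGGCCATATGAGTTCTTGGAGTTTCATCATCCACATAATATGTTAGCAATGTCGCCGTGCCATTATCTGGCCTGGCAGATCATGATTCATAATCGCGGGGATAACTTCCGCGACTCCATCTACCATACCACCTTTCCTTGTCCGGCTGGCATGGACTATTGGGACAATACTTTTTGTTCACCGTGC
>IGHV3-23*01
GAATATCCCCATGAAGAACAGGGTTCTCTCCCAGGGTTCTGGTATTTAACATGTCCGGCCGACAAATGCTGGTATAACAAATTTATGAACGTTGCCAAGTGCCCTTGGGAGTGGAAGTGGGTCGCATTTTGTCTATGGGAGGACGAGACGGAGGGTACGCATGCCCAACAACTTTACTCGTTTTGGCAACCAACAGACATGCCTACGTCCCACGGTTCATGGAGAATGTGTGGACCAGTTTCGCGATGTTGGGACTGGCGACCTTACTATTTTACATGGGCTGAAAAGATATGGTGC
>IGHV3-30*01
ACAGTGTTCACCATGTACTACGTACAAGACCTATCATCTACGTTTTGGCACTCCCACTGTTGGGGGTGCTGGTTTCGCTATTTAATGTTCTTTTGGAAAAACCGGTTCTTTTGGTACTTCGACGTGTACAAGCTTTGGGGGAGAGGACCTTGGCTCCAACCCTGGTACAAACATCAACAGACGTGGATGGCCGAGAAACACCACAAGCCAGGCGGAAATCGAGCCAAGTTTTACGGGTACAAGAAATTAGAGTGTAAGTTTCCGACTAATGATAAGGTTTGGGACTGGTATACATGC
>IGHV3-48*01
AGATGGGTATTCATGGTAATGTCTAGCTGGGTTGAGTGGGCCAGGGCCGTAATGCGCTCGAGTCACTGCAACTTCCATCACTGGTGGTTCTTCCAATATATCCATAAGTTGTGGCCCGGAGTTATGCGGAACTATATGCAGCAGAATGTTTCGCAATGCGAACCGTGCGGTTTCGCAATAATTCCGCAGCAATACTGGATCGACCCATATATCATGCCGGTTTATATGTTCAACCGCCACACGACCGTCGGGCGTAAGTATGGGAAGTGCAGTCTGCGAATGCCTGGCCCTTATTGT
>IGHV3-7*01
ACGGGGCACGTGTCAGCACGAATGCACGTGATACTCCACTGGGCAGTGCCAAATTGTTTCTTGAGTTGCGGGAATACAATTTGCTTGAACCACTGCTCGACTACCGGCGTAGAATGGCCCCGGTTAGTTAGCATGCTGACATATCCTCAAGACTGGGCGAAGCAGATAGCAGCATCCGCTCCTGGTATGGTGCAGCCGTCATGGGCATGCGATTGTAGTATGTTAGAGTGTTTATGTTTTGGCCCCTTGACGTCCTGGTGGGGCTTCGAACTGTGGGTGGACATACGGTCAAGATGC
>IGHV4-34*01
TGTAACTTTTTCCCTCTGATGGACATCCCATTCATGTATGCTGAGACCGATGAACCTGTATTTCAGTGCGCCGTATATAGCTGTCACATCAAGGAAGAGTGGCTAAACGACTGGCATGATGGGATATTCAAGAAAAGCATGGGGTGGATGATGTTACGTAACCATTCAGAGTACGAGAAAATGGTAAAATTTATTTATGTATCAATGGCGCACCCTTACTGTAAACAGAAACTCTCTCACAATAAAAAACGATCCACCTGCGTGACCCGTGATAAACAGGGATGCATGTCTGAGTGT
>IGHV4-39*01
CAAAGTTCCTTCTACTGGTATGAGCTCTACGTTTGGCCTTTTTTCGACATCCAACCTGTACAAATGTGTGAGAAGTATATTTATGACGACGAAAATATATGGTGGACTTACTGGGCGGACAATAATGCTTTAGATATATATGAGGAGTTACAGGTGAGATATTTTCTCAAGGCATCGCCCCCATACAAACAACCGTATGAGTGCGGTCAGTATTGGCGATATTTTTGGAAAATGTACTACCTGATGTTTCACCGAAAGAAGTATCGGAAACCAAGGTCCAATGATGGCCTCTATTGC
>IGHV4-4*01
CACTTACGGCAGTTTGGGTTCTGGAAAAAGCTCATGTGTCATATATTCCCGAACTACAAGTCACATTGTGAAGACACATCCGAGTCAGATAAAGACAACGTATCACTCAACTGGTATCAGGAAGAGTCCCGACGAATAATGCATTATTGGGATGGACATGCCTGGGAAACCGACTACAAGAAAACCGCAAATATATGGGTCAACGATAAATATCAACGTTGGTTTACTTTCGAATACAGGGCAATCCTATGGTCGTCGGAATATCACGGCGGCTATGCGTGGAAGAAGGCATGTTGC
>IGHV4-59*01
TCGGAAATGTGGTTCAAGGTGCCGCGTTATGATTCGTGTCCACTACACCCTCTCCCGTGTCTCATGTGCAATTACTTCGAAAAGCGGACAGATCCGTGCGTTAATTGGGACTGGTGGCATACGGTTATCTGTATAAAAGATACTATGCCCTGTTTTTGCAAATGGGATCACGAGCCGACTTGTTGCTATTCATGGGAATCTATGAACAGGCGACTTTATGCCATACCCTGCAATGTTGACAAGATGACTGATTCCGACGTTCGAGTACAAATAGCGATTCCGAATCAGGACATATGC
>IGHV5-10-1*01
AATACATGCATGCACACACAACGTTGTTGCTTCCCCACGCGTTGTACTCCCATTACATGTGTTTGCTGCGGGTATTGTACTGAATGGCATAAGCAACCCATGGGTGGGACATGGATGATTCTTGCCTCTTGCGCATGGTGTCATGCTGTTTCCTCAACGAAATTCCCGTCATATCATGATTTCAGAATAGATAATTGGTGCTATCTAAAAATAATGGGTCATGCGAGTCACTCTGCCCCTCCAACAGACGAGAATTACAGCGCACCCGAGCGCGCAACAATGTGCGAGTCCATTTGT
>IGHV5-51*01
GACGAATGCCAGGAGTTTACCGCCTGCAATGAGGCAGTAGTCCATCTGTTACCTTTCCAGGCCGAATGCGCGTTTGAGGTAGCCGCATCGAACGAGTTCTTGTATGATTGGTGGCAGACGGAGTCTGACATGCAGATTGGGGATCGCCGATGCTCTGATACCCACGCACTAAAGGAGGGGATTCTAACGCAAACATCCCAGAGTTGGAGCGGGGATGGAGGGGAGTTAATGCTAAATAGAGGTATCGCTAGAAATTTAATGAGACAATACCGATCGTACTATACAATGGAATATTGT
>IGHV6-1*01
CAGAGTAAGTGGAACTGGATGAAAATACAGGTGGAAATTCACTCTCACATGGGCGGGTTCCCGCACTGCACGCCAAGAGACCCCCATGAAGCTATGGGAAAGTTCTTGGGGTGGATGGTGGACTTCGCTAAATGGAAATTTGCTGTTCACCGAGTATCTTGGGAAATGCACCAGGACACAGGTAAGACGTGTGACACCTACTTCTTCGAGGGTCATACCTTATTTTCTGTGATCAACTTTTTCGCCGCGAGTTGCTGGATGTATGGGTATCTTAACATATGGGATCCGTGGCCATGC
>IGHV7-4-1*01
CAAATTATTAGGTTAATGCACGTACGTAACGATCGGGTGCATGAGATAAAATCGAAGCGCTGGCAGTGTCAGGCTTATTGGTGCATGCAACATATGCTTGCAGAATACTGTGACTGGTTCTCTTGGACACCCTACATGTTCCAGTTCGTACTAAAATGCATCGAGCGATCTGAGCGACATGTCGCTATTTTCAAGTTTGGCGGATCTCATATGATGTGCGCCTCTAATGTCCCTTCAACCATGAACGACGATGCTGCTTGTGATTACAACCATACAGACGATTTCGTTGTACTTTGT
>IGHV7-81*01
GATGGCGTGATTGCCCACATCTACGGTATGTCCGAACATTTTCAACCGCATAACCTGATGAGAGCGTGTATTGAGCCGCATGAAGGCGAGTGTCAGCTAACAGCTTACCATTGGGCAAGGTTTGAATCATATCAAAAGATGTCGGATGACTACGAGGTATATATGAGCTGGGCACACCAGGAATCATGGGATGTTGAATTTGTGGTAATGCATCACGCGAAATGCTGCTCGGTCAAGTTAGTGAACAACCCGATTTACCCTGAAATTTGGAGGAATGATACTGAACGGATAAGGTGC
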