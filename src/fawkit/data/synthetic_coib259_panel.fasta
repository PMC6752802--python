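>S_frugiperda_CS_consensus
GTGATTCTCGCACCGTATAGCAGAGATCGGTTCTCGCCACCTTATCCCCCTCCATAGGACACTCCCTACCGTTAACCGGGGAAGTTATCACTCCGCTTACATGCATGTCAATGCCAACTGTAGTAGGTTTGCTCGACCTGACGTGCGAGCGCACAACCGCAGGTGAGATAGACAGACAATCAAAAGGATCGCCCAACCCGTTTATCTCCGACCCCAACGGGCAACATACATTCTGAGGGGGGCTAAACTATTTACCGTC
>S_frugiperda_RS_consensus
GTGATTCTCGCACCGTATAGCAGAGATCGGTTCTCGCCACCTTATCCCCCTCCATAGGACACTCCCTACCGTTAACCGGGGAAGTTATCACTCCGCTTACTTGCATGTCAATGCCTACTGTAGTAGGTTTGCTCGACCTGACGTGCGAGCGCACAACCGCAGGTGAGATAGACAGCCAATCAAAAGGATCGCCCAATCCGTTTATCTCCGACCCCTACGGGCAACATACATTCTGAGGGGGGCTAAACTATTTACCGTC
>S_albula
GTGATTCTCGCAGCGTATAGCGGCAATCGGTTCTCCCCTCCTTATCCCCTTCCATAGGACACTCCCCACCGTTAACCGGGGAAGTTATCACTCCGCTTATATGCATATCAATGCCAACTGTAGTAGGTTTGTTCCACCTGATGTTAGAACGCACAACCGTAGGTGAGATAGACACACAATCAAAAGGATAGTCCAACCCGTTTATCTCCGACCCCAACGGGCAACATACATTCTCTGGCGGGTTAAACTATTTAACATC
>S_cosmiodes
GTGATCCTCGCACCGTATAGCAGAGATCGGTTCTCGCCACCTTACCCCCCTCCGTAGGACACTCCCTCACGTTAACCGGGGAAGTCATCACTCCGCTTACATGCATGTCGAGACCAACTGTCGGAGGTTTGCTCGACCTGACGTGCGAGCGCACCACCGCAGGTGAGATAGACAGATAATCAAAAGGATCGCCCAACCCGTTTATCTGCGACCCCAACTGGCAACATACATTCTGAAGGAGGCAAAACCATTTACCCTC
>S_descoinsi
GTGATCCTCGCACCGTATAGCAGAGATCGGTTCTCGCCACCTTACCCCCCTCCGTAGGACACTCCCTCACGTTAACCGGGGAAGTCATCACTCCGCTTACATGCATGTCGAGACCAACTGTCGGAGGTTTGCTCGACCTGACGTGCGAGCGCACCACCGCAGGTGAGATAGACAGATAATCAAAAGGATCGCCCAACCCGTTTATCTGCGACCCCAACTGGCAACATACATTCTGAAGGAGGCAAAACCATTTACCCTC
>S_dolichos
GAGATTCTCGCACCGTCTAGTAGAGAGCTGTTCTCGCCAACGTATCCCCCTCCATAGGACACTCCCAACTGTTAACCGGAGAAGTTGGCACTTTGCTTACATGCATGTCAATGCGAACTGTAGTAGGTTTGCTCGGTCGGATGTGCGAGCGCACAACCTCAGGTAAGATAGAAAGAATATCAAAAGGATCGCCCAAGCCGTACATCTCCGACCCCAACGGGCAACATACATTATGAGGGGGGCTAAACTATTTACCGTC
>S_eridania
GTGAGTCTCGCACCGTGTAGCAGCGATCAGTTCTCGCCACCTTATGCTCCTCCATAGGACAGTCCCTTCCGTTAACCGGGGAAGTTAGCATTCCGCTTACATGCATCTCAATGACAACTGTAGTAGGTTAACTCGACCTGACGTGCGAGCTGACAACCGCAGGTGAGAAAGACAGACAATAATAAGGATCGCCCAACCCGTTTATCTCCGACCCCAAGGGGCACCATGCATACTCAGGGTGGTTAAACTATTAACCGGC
>S_exempta
GTGTTACGCGCACCGTATAGCAGAGATCGGTTCTCGTCACCTTATCCCCTTCCATAGGACACTCCTTACTGTGAACCGGGGAAGTTATCACTCCGCATACATGCATGTCAATGCCAACTGTAGTAGGTTTGCTCGATGTGGCGCGCGAGCGCACAACCGCAGGTGCGATAGACAGACAATCAAGAGGATCGCCCAACCCGTTTTTCTCCGACCCCAACGGGCAACATACATTCTGAGGGGGGCTAAATTATTTACCGTC
>S_exigua
GTGATTCTCTCACTGTATAGCAGAGCTCGGTTCCCGCCACCTTCTCCCCCTCCATAGGACACTCCCTACCGTTAACCGGGGAAGCTAGCACTCCGCTTACATGCATGTCAATGCCAGCTGTAGTAGGTTTGCTCGACCTGACGTGCGAGCACACAACCGCAGTTGAGATTGACAGACAATCAAAAGGATCTCCCAACTCGTTTATCTCCTAACCCAACGGGCAACATACAATCTGGGGGGGGCTCAACTATTTAACGTC
>S_latifascia
TTGATTCTCGCACCGTATATCAGAGATCAGTCTTCGCCACCTTATCCCAGTCCATAGGACACTCCCGACCGTCAAGCGGGGAAGTTATCACTCCGCGTACATTCATGTCCATGCCAACTGAAGAAGGTTTGCTCGACCTGACGTGCGACGGCACAACCGCAGGGGAGATAGGCAGACAATCAAAAGCATCGCCCAACCAACTTATCTGCAACCCCAACGGGCAAGATACATTCTGAGTGGGGCTAAATCATTTTCCGTC
>S_littoralis
GTGCTTCTCGCACCGTATAGCAGACATCGGTTGTCGTCACCTTATCCCCCGCCATAGGCCACTCCCTACCGTTCATCGGGGAAGTTATCAATCCGCTTACATGCATGTCAATGCCAACTGTAGTAGGTTTGCTCGACCTGACGTTCGAGCGCACAACCGCTGGTGAGATTGACAGACGTTCAAAAAGATCCCCCAACCCGTGTATCTCCGAACCCAACGGGTAACTTACATTCGGATGGGGACTAAACTATTTACCGAC
>S_mauritia
GTGATTCTTGCACCGTATACCAGAGATGGGTTCTCGCAACCTTATCTCCCTCCATAGGAGACTCGCTACCGTTAACCGGGGAAGGTATCACTCCGCTAACATGCATGTCAATGCCAACAGTAGGCGGTATGCTAGACGTGACGAGCGAGCGGAGATCCGAAGGTGAGATTGACAGACAATCAAAAGAATCGCCCAACCCGTTTATCTCCGACCCCAACGGGCAACATACATTGTGAGGGGGGCTAAACTATTTACCGCC
>S_ornithogalli
TTGATTGTCGCACCGTAAAGCGGAGATCGGTTCTCGCCACCATATCCCCCTCCATAGGACACTGCCTACCATTAACAGGGGAAGTTATCACTCCGCTTACATGCATCTCTATCCCAACTGTGGTAAGATTGCTCGACATGACGTGCGAGCGCAGAACCTCAGGGGAGATTGACAGACACTCAAAAGGATCGCCCAACCCGTTTATCTCTGACCCCAACGGGCACCATACATTCTGAGCGGGGCTAAACTAATTACCGTC
>S_praefica
GTGATTCTCGCACTTTGTAGCAGAGATCCCTGCTCGCCCCCTTATCCCTCTCCATAGTACACTCACTATCGTTAACCGGGGAAGTTGTCACTCCGCTTACATGCATGGCAATGCCAACTGTAGTAGGTTTGCTCGACCTGACGTGCGAGGGCACTACTGCAGGTGTGATAGACTGACAATCAAAAGGATCGCCCAACCCGTTTATCTCCGACCCCAACGTGCAACATACATTCTAAGGGGGGCTAAATTATTTACCGTC
>S_litura
GTGATTCTTGCACCGTGTAGCGCAAATCGGTTCGCGCCACCTTATCCCCCTTCATAGGACACTCTCTACCGTTAACCGGGGGAGTTATCACTCCGCTCACAGGCATGTCAATGCCAACTGTGGTAGGTTTGCTGGACTTGACGTGCGAGCGCACAACCGCAGGTGAGATAGACAGACAATCAACAGGATCGCCCAACCCGTATATCTCTGTCCCCAACGGGCAACATATATTCTGAGGGGGGCTAAACCATTTACCGTC
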