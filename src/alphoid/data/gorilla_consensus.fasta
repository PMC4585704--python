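>GGO_consensus sf=general unit_type=unspecified size=172
AATCTGCAAGTGGATATTTGGASYSYTTTGAGGVCTTCGKTGGAAAMGGRAATWTCTTCA
TATAAAAACTAGACAGAAGCATTCTCAGAAACTTCTTTGTGATGTGTGCATTCAACTCAC
AGAGTTGAACCTTYCTTTTGATAGAGCAGTTTTGAAACACYYCTTTTTGTAG
>GGO_consensus_Atype sf=general unit_type=A size=172
AATTTGCAAGTGGABATTTCGAGCGCTTTGJGGCCTATGGTAGAAAFAGGAAATATCTTC
ATATAAAAACTAGACAGAAGCATTCTCAGAAACTWCTTTGTGATGTGTGIRTTCAACTCA
CAGAJKTGAACCTTTCTTTTGATAGAGCAGTTTTGAAACACTCTTTTTGTAG
>GGO_consensus_Btype sf=general unit_type=B size=170
AATCTGCAAGTGGATATTTGGACCTCTTTGAGGATTTCGTTGGAAACGGKATTTCTTCAT
ATAARAWCTAGACAGAAGAATTCTCAGWAACTTCTTTGKGATGTWTGCBTTCAACTCACA
GAGTTGAACMTTCCTTTTGATAGAGCAGRTTTGAAACACTCTTTTTGTGG
>gJ1 sf=SF1 unit_type=A size=171
AATTTGCAAGTGGACATTTCAAGCGCTTTGGGGCCAACGGTAGAAAAGGAAATATCTTCG
TATAAAAACTAGAGAGAATCATTCTCAGAAACCACTTTGTGATGTGTGCGTTCCACTCAC
AGAGTTTAACCTTTCTTTTCATAGAGCAGTTTGGAAACACTCTGTTTGTAA
>gJ2 sf=SF1 unit_type=B size=169
AGTCTGCAAGTGGATATTTGGACCTCTTTGAGGATTTCGTTGGAAACGGGATTTCTTCAT
CTAATGCTAGACAGAAGAATTCTCAGTAACTTCTTTGGGTTGCGTGTGTTCAACTCACAG
AGTTGAACCTTCCTTTAGACAGAGCAGATTTGAAACCCTCTTTTTGTGG
>gD1.0 sf=SF2 unit_type=B size=171
AATCTGCAAGTGGATATTTGGATAGGTTTGAAGATTTCGTTGGAAACGGGAATATCTTCA
TATAAAATCTAGACAGAAGCATTCTCAGAAACTTCTTTGTGATATCTGCATTCAAGACAC
AGAGTTGAATATTCCCCTTCATAGAGCAAGTTTGAAACACTCTTTTTGTGG
>gD1.1 sf=SF2 unit_type=B size=171
AATCTGCAAGTGGATATTTGGATAGCTTTGAAGATTTCGTTGGAAACGGGAATTTCTTCA
TATCAAATCGAGACAGTAGCATTCTCAGAAACTTCCTTGTGATATCTGCATTCAAGTCAG
AGAGTTGAACATTCCCTTTCATAGAGCAGGTTTGAAACACTCTTTCGGTGG
>gD1.2 sf=SF2 unit_type=B size=171
AATCTGCAACTGGATATTTGGATAGATTTGAAGAATTCGTTGGAAACGGGAATATCTTCC
AATAAAATCTAGACAGAAGCATTCTCAGAAACTTCTTTGTGATGCTTGCATTCAACTCAT
AGAGTTGAACATTCCCTATCATAGAGCAGGTTGGAAACACTCATTTTGTAG
>gD1.3 sf=SF2 unit_type=B size=168
AATCTGCAAGTGGATATTTGGATAGATTTGAGGATTTCCGTTGGAAACGGGATTACATAT
AAAAAGCAGACGGCAGCATTCTCCGAAATTTCTTTGCGATGTTTGCATTCAAGTCACAGA
GTTGAACATTCCCTTTCATAGAGCAGGTTTGAAACACTCTTTTTGTGG
>gD1.4 sf=SF2 unit_type=B size=189
AATCTGCAAGTGGATATTTGGGTAGATCTGAGGATTTCGTTGGAAACCTTTGAGGATTTC
GTTGGAAACGGGATTACATATAAGAAGCAGACAGAAGCATTCTCCGAAATTTCTTTGTGA
TGTTTGCATTCAAGTCGCAGAGTTGAACATTCCCTTTCATAGAGCAGGTTTGAAACACTC
TTTCTGTAC
>gD2.0 sf=SF2 unit_type=A size=171
AATGTGGAAGTGGACATTTGGAGCGCTTTGAGGCCTATGGTGAAAAAGGAAATATCTTCC
CATAAAACCTAGACAGAAGCATTGTCAGAAACTTCTTTGTGATGTGTGTACTCAACTAAC
AGAGTTGAACCTTCCTTTTGACAGAGCAGTTTTGAAACACTCTTTTTGTAG
>gD2.1 sf=SF2 unit_type=A size=171
TATCTAGAGGAGGACATTTCGAGCGCTTTCTGGCCTATGCTGAGAAGGGAAATATCTTCA
AATAAAAACTAGACAGAAGCATTCTCAGAAAGTTGTTTGTGATGTGTGTCCTCAACTAAC
AGAGTTGAACCTTTGTTTTGATACAGCAGTGTGGAAACACTCTTTTTGTAG
>gD2.2 sf=SF2 unit_type=A size=171
TATCTGCAAGTGGGCATTTCGAGCGCTTTCAGGCCTATGCTGAGAAACGGAATATCTTCA
AATAAAAACCAGACCGAAGCATTCTCAGAAACTTATTTGTGATGTGTGTCCTCACCTAAC
AGAGTTGAACGTTTGTTTTGATACAGCAGTTTGGAAACACTCTTTTTGTAG
>gW1 sf=SF3 unit_type=B size=167
AATCTGTAAGTGGATATTTGGACCCCTCTGAGGATTTCGTTGGAAACGGGATAAACTTCC
CATAACTAAACGGAAGCATTCTCAGAAACTTCTTTGTGATGTTTGCATTCAGCTCACAGA
GTTGAACCTTCCTTTGATAGTTCAGGTTTGAAACACTCTTTTTGTAG
>gW2 sf=SF3 unit_type=B size=171
AATCTGCAAGTGCATATTTGGACCACCGAGTGGCCTTCGTTCGAAACGGGTATATCTTCA
CGTAAAAGCTAGGCAGAAGCATTCTCGGGAACTTCTCTGTGATGATTGCATTCAACTCAC
AGAGTTGGACACTCCTTTTGATAGAGCAGTTTTGAAACTCTCTTTTGGTAG
>gW3 sf=SF3 unit_type=B size=171
AATCTGCAAGTGGATATGTGGACCTCTTTGAAGATTTCTTTGGAAACGGGAATATCTTCA
CATAAAAACTAAACAGAAGCATTCTCAGAAACTACTTTGTGATGATTGCATTCAACTCAC
AGAGTTGAACATTCCTATTGATAGAGCAGTTTGGAAACACTCTTTTGGTAG
>gW4 sf=SF3 unit_type=A size=169
AATCTGCAAGTGGACATTTGGAGCGCTTTGAGGCCTGTGGTGGAAAAGGAAATATCTTCA
CATAAAAACTAGATAGAAGCATTCTCAGAAACTCTTTGTGATGATTGCATTCAACTCACA
GAGTTGAACATTCCTTTTGATAGAGCAGTTTGGAAACACTCTTTTTGTG
>gW5 sf=SF3 unit_type=A size=171
AATCTGCAAGTGGAGATTTGGACTGCTTTGAGGCCTAYGGTAGTAAAGGAAATAACTTCA
TATAAAAACCAAACAGAAGCATTCTCAGAAAATTCTTTGTGATGATTGAGTTGAACTCAC
AGAGCTGAACATTGCTTTTGATGGAGCAGTTTCCAAACACACTTTTTGTAG
>gM1 sf=monomeric unit_type=unspecified size=171
AATCTGCAAGTGGATATTTGGAGCGCTTTGAGGCCTATGGTGGAAAAGGAAATATCTTCA
CATAAAAACTAGACAGAAGCATTCTGAGAAACTTCTTTGTGATGTGTGCATTCATCTCAC
AGAGTTGAACCTTTCTTTTGATTGAGCAGTTTTGAAACACTCTTTTTGTAG
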