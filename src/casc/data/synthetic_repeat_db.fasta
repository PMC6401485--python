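>syn_repeat_01 synthetic CRISPR repeat (randomly generated stand-in)
GTAGCCCTTCCAAAGGACAAGCTCCGTAG
>syn_repeat_02 synthetic CRISPR repeat (randomly generated stand-in)
AAACTCTCTCAAACTCGATAAACCTAAGTC
>syn_repeat_03 synthetic CRISPR repeat (randomly generated stand-in)
TGAGACATACTGGCCATTCGATAATACTGCTT
>syn_repeat_04 synthetic CRISPR repeat (randomly generated stand-in)
GACAAATGCCTTCTGCGAAGTTGGAACAA
>syn_repeat_05 synthetic CRISPR repeat (randomly generated stand-in)
GACTTTGAGGATAAAATATTTCGGGCTCAAGG
>syn_repeat_06 synthetic CRISPR repeat (randomly generated stand-in)
GCGAGAGTATCCTCGGGCTCACACAGCGAC
>syn_repeat_07 synthetic CRISPR repeat (randomly generated stand-in)
ATGCTAAGAAATGGCTCACCAAATACGGG
>syn_repeat_08 synthetic CRISPR repeat (randomly generated stand-in)
AACTATCGATTGCATCTAAGGATCTAATATCC
>syn_repeat_09 synthetic CRISPR repeat (randomly generated stand-in)
CAGAGCCATTTCATGGACAATATTTGCGAAGA
>syn_repeat_10 synthetic CRISPR repeat (randomly generated stand-in)
GAGCGGCTTTCTCGCTCGTAATTATAAACG
>syn_repeat_11 synthetic CRISPR repeat (randomly generated stand-in)
CATCCTCTGGTCGCTTGATCCGTGGGCC
>syn_repeat_12 synthetic CRISPR repeat (randomly generated stand-in)
GGTCGCAATCGCCCTCTGAGAGTGGTTTCA
>syn_repeat_13 synthetic CRISPR repeat (randomly generated stand-in)
CAGGACATTGCTCAGGTCAGCATGGGGT
>syn_repeat_14 synthetic CRISPR repeat (randomly generated stand-in)
AGGCACGCCGTTGCTTCGATAACACTAAC
>syn_repeat_15 synthetic CRISPR repeat (randomly generated stand-in)
ATAACGATTCCCTGCGAAATTACTGGCG
>syn_repeat_16 synthetic CRISPR repeat (randomly generated stand-in)
TGACAGAGCGCGCTTTGGGCCCGTTACCCCTA
>syn_repeat_17 synthetic CRISPR repeat (randomly generated stand-in)
GTTGTTATGCCCAGAATCGTATAGTAAAGCA
>syn_repeat_18 synthetic CRISPR repeat (randomly generated stand-in)
ACTACCCCGGGTGAGAAGAGTAATTTCCGG
>syn_repeat_19 synthetic CRISPR repeat (randomly generated stand-in)
AATAGCTCATACAGTGTAGTATTTTAATCC
>syn_repeat_20 synthetic CRISPR repeat (randomly generated stand-in)
CGTGTGTCGTCTCGTCGTGCGGCGTCCGAGC
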