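>synthV1 synthetic V-like reference segment (randomly generated, not a germline gene)
CGAAGCGGACCATGGACCGGCTTCCCTTGTAAACCCCTACTCTTCGTCACTGTTATGAGC
CAACTCGCGTAGATCGGCTACGGCATGTCGTAAACACTCATATCAGTCAGCTTCGCTCAC
CTACCAATTTAGGGGTACGGGTTTGCAGATCCTATTACCTTTTTTATGCAGGTACGTTGG
ACTGAGCATCCACCTTTTCATCCCAGCTTGCTGCGTCGTCGGACTGCATTAGATCTTTTT
AGAGCCGTGT
>synthV2 synthetic V-like reference segment (randomly generated, not a germline gene)
GGCAAGCCAGGAACGGTCGGAATTAGGCCTCACGCAAGCGCGGGTTGCCAACCGTGATCT
GATTCCTCGGATTGGGTTAGGAATGGCATCTACTTTGTCGTTGCTACGCCCGACAGGTGT
AAGCTGTAAATTGTTAGGATCACAGCAGCAAAGTGGTGTTTTTGCACACGGCGTAAATGT
AAGTCACTGAGTTGGGAGGTAAGAGGTCGGAATGAGATGTATGCGAGCGTGACGCGCTTT
CATAAGTGAG
>synthV3 synthetic V-like reference segment (randomly generated, not a germline gene)
CAGAACCTCTAAATCTAACGCTGTTCCAGATAGGACTAAACGTTGCCAGCGAAACGTCCT
GCCACGGAAGCCGCACTCGTACGCCTTCACACTAACTGCTTTCAGACCGCGCGAGAAGGA
TAGCAGTGGGCTTGGCAAATGCTGATCACTGGCAAAGTCACATGGTAAGTTGGCACAACG
CAGTACGGAACTCCCAGGCGGGCCTCGATCGCTGTAGACGAGCGTGATAGCCGTAGTAGT
CAAAGGTAGA
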