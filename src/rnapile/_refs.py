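"""Packaged contaminant reference sequences for the read simulator.

``ADAPTER`` is the standard Illumina single-read library PCR primer.  The
rRNA and foreign-organism references are *synthetic* stand-ins — fixed random
sequences, not biological rRNA or any real organism's DNA — long enough for
36-bp windows to be drawn from them and for ungapped identity screening of
unmapped reads to work against them.
"""

ADAPTER = "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"

RRNA = (
    "ATAGCCGGACGCCTTGCTGGGGCAACCATAGCGTAGTCCAGTATGTATAGCTGTCGTATG"
    "GCATGGACATTTGATACGGGGAATGAATCCTCACTCCTCTCCGTACCGGGTTAGGTTCGT"
    "CTAATGCGAGTCCGGGATTCTGGGCTCAGAAGCATTCGTTTCGGCCCTTCCTCCCACGCC"
    "TCTGTCCAAATCATTTTTACGGCCGGCGGCCCGCGTAGTATGGGATCTCTCCATATATTG"
    "GTCAGACAAAGTACTTAGGGTCGCTTCAAGAGGGCCTGGTGTCCCGAAGGCATTACCGTG"
    "AGAAGGGCTCTTATAGGAATTATCAAGAGGTAAACCCATAGGTCACCCAAGACGTAGCAT"
    "TCAGATCATTTCCTGTCGACACCTTGTGTGACGTTATTTGGTTCTAACGATGCCTGTGGG"
    "GTTGTGTATAAATTCGGCGAAATGCCGGAGGCTCACAAGGGACTGCTCTGAAACCTATTC"
    "TCCAGCCTGTGATGTAAATTACACTGACCTGACGCAAGGAGGTTGGAGGCTTGGTGATGA"
    "ACACCTACGCTTCGGGCAACCTGAGCACAATCAGTCAACTACGTACGGTGACCTTTTGGC"
    "ACGAGGGTAAGAAGGACGAT"
)

FOREIGN = (
    "AGCAGATGTACGCCGTCAAGTGTTCCCTGAAACGCATGCGAACAGAGACCGTAAGCGCAG"
    "AACACGTCAGGACTACCGCTCAAACTATTAGTGATGATCGGGAGATGTGTCCGCTTCAGT"
    "TTAGTCTACCTGTGTCCGGCCGGTACCTTTACTAGTACTGGGGGTTGGAGCATATTTCAG"
    "CTTATCTGGCCAATGCCAAAGTCGCAGTATATGCAGTACGCTAGAAGATATCCCTACGGA"
    "GAATGGAAGGGCAAATGAGATCATCGAACCCAGGGCTGCGCCAACGATACCGCAACCCGC"
    "GGAAGAACTTACGCTCAATTTCAGGGGGTGACCCATAGTGATATTCAGTAATTCCAAGCC"
    "TATTATACCTGGCACGTACGGTGTCTTCATCGCTGAAGTCGTTCTTGATACTACTTACTG"
    "TTACTTATAGGGGTCCTTGACTAATTTATGGTGTAGTAACACAGGACTATTTGCGTAAGG"
    "CCGGAATATCGAAACTGACGCCTCTACGGCTAGTAATTGGTGTATACACTATTCACTAGC"
    "TAGCCGCGACCACCGGCGCAGCTCGCTGGCAAATATGGACTAGCGGATCCTGGTTCATAT"
    "TTTATGCATGGATAGACCGGATCGCTGGTGGCAACGCGATGGGAATTCGCTCAAATAATG"
    "CCCACCCGAAATCTAGAGAA"
)
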