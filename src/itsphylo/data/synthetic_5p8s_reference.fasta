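>synthetic_5p8s|synthetic 163-nt 5.8S anchor reference (not a natural sequence)
TTCTTAATTCTTTCAGGTATAGCCGGCGAAGGTGGGTCCGCCGGGAACTGGGCCCGTTCAGTTTGACTAC
GCCCGGAATCCTTGGCCTCTCCGGAAGCTTGTCAGGAAGGCCTGAGGCGGCCACCAGGGTGTGCTTACGG
GAAGCGGGGCACCCTAAGTGCTG
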