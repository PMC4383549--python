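>rs72664324_A protective allele probe (variant at position 13)
aggaaatgaaccAatgtctgttcct
>rs72664324_G risk allele probe (variant at position 13)
aggaaatgaaccGatgtctgttcct
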