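>CEBP_SITE_SYN synthetic C/EBP-like motif centred on the rs72664324 A-allele site (consensus AACCAATGTC)
A  [ 32 30  2  2 34 30  4  2  4  2 ]
C  [  2  4 32 34  2  2  2  4  4 30 ]
G  [  2  2  4  2  2  4  2 32  2  4 ]
T  [  4  4  2  2  2  4 32  2 30  4 ]
>CCAAT_BOX_SYN synthetic CCAAT-box (NFY-like) motif
A  [  2  2 36 36  2 ]
C  [ 34 34  1  1  2 ]
G  [  2  2  1  1  2 ]
T  [  2  2  2  2 34 ]
>CTRL_UNIFORM_SYN synthetic near-uniform control motif
A  [ 10 10 10 10 10 10 ]
C  [ 10 10 10 10 10 10 ]
G  [ 10 10 10 10 10 10 ]
T  [ 10 10 10 10 10 10 ]
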