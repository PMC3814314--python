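MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF zic3_consensus
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
0.0748 0.0422 0.8636 0.0194
0.0480 0.8450 0.0220 0.0850
0.0246 0.8264 0.0952 0.0538
0.9647 0.0179 0.0113 0.0061
0.0127 0.0069 0.9603 0.0201
0.0057 0.9670 0.0167 0.0106
0.9625 0.0190 0.0120 0.0065
0.0134 0.0073 0.9580 0.0213
0.0061 0.0179 0.9647 0.0113
0.0901 0.0509 0.0233 0.8357
0.0422 0.0194 0.8636 0.0748
0.0220 0.0850 0.8450 0.0480
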