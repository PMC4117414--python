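REMARK   6 word template: Carboxamide
ATOM      1  CD  GLN A   1      -0.213  -0.036  -2.614  1.00  0.00           C
ATOM      2  OE1 GLN A   1      -1.252  -0.650  -2.500  1.00  0.00           O
ATOM      3  NE2 GLN A   1       0.277   0.236  -3.839  1.00  0.00           N
END
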