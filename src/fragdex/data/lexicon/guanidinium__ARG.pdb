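REMARK   6 word template: Guanidinium
ATOM      1  NE  ARG A   1       4.071   0.726  -2.421  1.00  0.00           N
ATOM      2  CZ  ARG A   1       5.469   0.624  -2.528  1.00  0.00           C
ATOM      3  NH1 ARG A   1       6.259   0.404  -1.405  1.00  0.00           N
ATOM      4  NH2 ARG A   1       6.078   0.744  -3.773  1.00  0.00           N
END
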