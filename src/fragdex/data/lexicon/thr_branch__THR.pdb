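REMARK   6 word template: Threonine branch
ATOM      1  CA  THR A   1       0.122  -0.706   0.056  1.00  0.00           C
ATOM      2  CB  THR A   1      -0.675   0.104   1.079  1.00  0.00           C
ATOM      3  OG1 THR A   1      -0.193   1.448   1.103  1.00  0.00           O
ATOM      4  CG2 THR A   1      -0.511  -0.521   2.466  1.00  0.00           C
END
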