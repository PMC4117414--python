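REMARK   6 word template: Alanine methyl
ATOM      1  CA  ALA A   1       0.257   0.418   0.692  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.204  -0.620   1.296  1.00  0.00           C
END
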