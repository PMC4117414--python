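REMARK   6 word template: Isoleucine side chain
ATOM      1  CA  ILE A   1      -0.487   0.519  -0.369  1.00  0.00           C
ATOM      2  CB  ILE A   1       0.140  -0.219   0.814  1.00  0.00           C
ATOM      3  CG1 ILE A   1      -0.421   0.341   2.122  1.00  0.00           C
ATOM      4  CG2 ILE A   1       1.658  -0.027   0.788  1.00  0.00           C
ATOM      5  CD1 ILE A   1       0.206  -0.397   3.305  1.00  0.00           C
END
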