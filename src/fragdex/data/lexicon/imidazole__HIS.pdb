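REMARK   6 word template: Imidazole ring
ATOM      1  CG  HIS A   1       2.940  -1.060   2.353  1.00  0.00           C
ATOM      2  ND1 HIS A   1       3.380  -2.075   3.129  1.00  0.00           N
ATOM      3  CD2 HIS A   1       3.960  -0.251   2.046  1.00  0.00           C
ATOM      4  CE1 HIS A   1       4.693  -1.908   3.317  1.00  0.00           C
ATOM      5  NE2 HIS A   1       5.058  -0.801   2.662  1.00  0.00           N
END
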