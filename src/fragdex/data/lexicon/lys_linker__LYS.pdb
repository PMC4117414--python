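REMARK   6 word template: Lysine linker (CA-CB-CG-CD)
ATOM      1  CA  LYS A   1       1.394   0.355   0.484  1.00  0.00           C
ATOM      2  CB  LYS A   1       0.184  -0.278  -0.206  1.00  0.00           C
ATOM      3  CG  LYS A   1      -1.102   0.282   0.407  1.00  0.00           C
ATOM      4  CD  LYS A   1      -2.313  -0.351  -0.283  1.00  0.00           C
END
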