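REMARK   6 word template: Serine linker
ATOM      1  CA  SER A   1       0.100   0.469  -0.252  1.00  0.00           C
ATOM      2  CB  SER A   1      -0.642  -0.489  -1.184  1.00  0.00           C
ATOM      3  OG  SER A   1      -0.496  -0.049  -2.535  1.00  0.00           O
END
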