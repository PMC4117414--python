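REMARK   6 word template: Hydroxyl
ATOM      1  CB  SER A   1      -0.642  -0.489  -1.184  1.00  0.00           C
ATOM      2  OG  SER A   1      -0.496  -0.049  -2.535  1.00  0.00           O
END
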