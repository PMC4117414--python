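REMARK   6 word template: Hydroxyl
ATOM      1  CB  THR A   1      -0.675   0.104   1.079  1.00  0.00           C
ATOM      2  OG1 THR A   1      -0.193   1.448   1.103  1.00  0.00           O
END
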