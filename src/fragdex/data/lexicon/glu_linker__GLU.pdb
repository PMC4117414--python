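REMARK   6 word template: Glutamate linker (CA-CB-CG)
ATOM      1  CA  GLU A   1       1.138   0.515   0.453  1.00  0.00           C
ATOM      2  CB  GLU A   1      -0.113  -0.200  -0.062  1.00  0.00           C
ATOM      3  CG  GLU A   1      -1.360   0.517   0.461  1.00  0.00           C
END
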