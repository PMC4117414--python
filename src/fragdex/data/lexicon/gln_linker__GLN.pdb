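REMARK   6 word template: Glutamine linker (CA-CB-CG)
ATOM      1  CA  GLN A   1       0.517   0.451   1.112  1.00  0.00           C
ATOM      2  CB  GLN A   1      -0.236  -0.013  -0.135  1.00  0.00           C
ATOM      3  CG  GLN A   1       0.529   0.421  -1.385  1.00  0.00           C
END
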