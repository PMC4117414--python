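REMARK   6 word template: Aspartate linker (CA-CB)
ATOM      1  CA  ASP A   1      -0.470   0.286  -0.344  1.00  0.00           C
ATOM      2  CB  ASP A   1       0.539  -0.580   0.413  1.00  0.00           C
END
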