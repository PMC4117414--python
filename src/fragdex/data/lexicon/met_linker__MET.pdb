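REMARK   6 word template: Methionine linker (CA-CB-CG)
ATOM      1  CA  MET A   1      -0.392   0.499  -1.214  1.00  0.00           C
ATOM      2  CB  MET A   1       0.334  -0.145  -0.032  1.00  0.00           C
ATOM      3  CG  MET A   1      -0.273   0.359   1.277  1.00  0.00           C
END
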