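REMARK   6 word template: Ammonium
ATOM      1  CE  LYS A   1      -3.598   0.208   0.329  1.00  0.00           C
ATOM      2  NZ  LYS A   1      -4.761  -0.400  -0.332  1.00  0.00           N
END
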