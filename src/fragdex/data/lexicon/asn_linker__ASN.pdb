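REMARK   6 word template: Asparagine linker (CA-CB)
ATOM      1  CA  ASN A   1      -0.448   0.292  -0.340  1.00  0.00           C
ATOM      2  CB  ASN A   1       0.562  -0.588   0.401  1.00  0.00           C
END
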