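REMARK   6 word template: Carboxamide
ATOM      1  CG  ASN A   1       1.960  -0.197  -0.002  1.00  0.00           C
ATOM      2  OD1 ASN A   1       2.132   0.697  -0.804  1.00  0.00           O
ATOM      3  ND2 ASN A   1       3.019  -0.841   0.527  1.00  0.00           N
END
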