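REMARK   6 word template: Carboxylate
ATOM      1  CG  ASP A   1       1.938  -0.195   0.004  1.00  0.00           C
ATOM      2  OD1 ASP A   1       2.109   0.681  -0.810  1.00  0.00           O
ATOM      3  OD2 ASP A   1       2.992  -0.826   0.543  1.00  0.00           O
END
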