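REMARK   6 word template: Hydroxyl
ATOM      1  CZ  TYR A   1      -0.032   0.118  -3.252  1.00  0.00           C
ATOM      2  OH  TYR A   1       0.044   0.420  -4.574  1.00  0.00           O
END
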