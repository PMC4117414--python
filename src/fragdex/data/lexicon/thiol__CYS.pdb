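REMARK   6 word template: Thiol
ATOM      1  CB  CYS A   1      -0.533  -0.530  -0.774  1.00  0.00           C
ATOM      2  SG  CYS A   1      -0.247   0.004  -2.484  1.00  0.00           S
END
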