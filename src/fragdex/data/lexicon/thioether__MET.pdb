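REMARK   6 word template: Thioether
ATOM      1  CG  MET A   1      -0.273   0.359   1.277  1.00  0.00           C
ATOM      2  SD  MET A   1       0.589  -0.405   2.678  1.00  0.00           S
ATOM      3  CE  MET A   1      -0.314   0.353   4.056  1.00  0.00           C
END
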