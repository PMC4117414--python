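REMARK   6 word template: Valine branch
ATOM      1  CA  VAL A   1       0.145  -0.698   0.079  1.00  0.00           C
ATOM      2  CB  VAL A   1      -0.682   0.086   1.098  1.00  0.00           C
ATOM      3  CG1 VAL A   1      -0.497  -0.528   2.487  1.00  0.00           C
ATOM      4  CG2 VAL A   1      -0.218   1.543   1.119  1.00  0.00           C
END
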