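REMARK   6 word template: Phenyl ring
ATOM      1  CG  PHE A   1      -0.181  -0.430  -1.020  1.00  0.00           C
ATOM      2  CD1 PHE A   1       1.031  -0.498  -1.680  1.00  0.00           C
ATOM      3  CD2 PHE A   1      -1.314  -0.018  -1.698  1.00  0.00           C
ATOM      4  CE1 PHE A   1       1.112  -0.150  -3.015  1.00  0.00           C
ATOM      5  CE2 PHE A   1      -1.231   0.333  -3.032  1.00  0.00           C
ATOM      6  CZ  PHE A   1      -0.018   0.265  -3.691  1.00  0.00           C
END
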