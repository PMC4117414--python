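REMARK   6 word template: Arginine linker (CA-CB-CG-CD)
ATOM      1  CA  ARG A   1       0.004   2.294  -1.708  1.00  0.00           C
ATOM      2  CB  ARG A   1       1.475   2.150  -2.127  1.00  0.00           C
ATOM      3  CG  ARG A   1       1.745   1.017  -3.130  1.00  0.00           C
ATOM      4  CD  ARG A   1       3.210   0.954  -3.557  1.00  0.00           C
END
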