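REMARK   6 word template: Tyrosine ring
ATOM      1  CG  TYR A   1      -0.189  -0.496  -0.559  1.00  0.00           C
ATOM      2  CD1 TYR A   1       1.022  -0.589  -1.219  1.00  0.00           C
ATOM      3  CD2 TYR A   1      -1.324  -0.102  -1.244  1.00  0.00           C
ATOM      4  CE1 TYR A   1       1.103  -0.282  -2.563  1.00  0.00           C
ATOM      5  CE2 TYR A   1      -1.247   0.210  -2.587  1.00  0.00           C
ATOM      6  CZ  TYR A   1      -0.032   0.118  -3.252  1.00  0.00           C
END
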