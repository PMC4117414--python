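REMARK   6 word template: Pyrrolidine ring
ATOM      1  N   PRO A   1      -0.816   1.108   0.254  1.00  0.00           N
ATOM      2  CA  PRO A   1       0.001  -0.107   0.509  1.00  0.00           C
ATOM      3  CB  PRO A   1      -0.703  -1.227  -0.286  1.00  0.00           C
ATOM      4  CG  PRO A   1      -2.163  -0.753  -0.439  1.00  0.00           C
ATOM      5  CD  PRO A   1      -2.218   0.614   0.276  1.00  0.00           C
END
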