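REMARK   6 word template: Phenylalanine linker (CA-CB-CG)
ATOM      1  CA  PHE A   1      -0.020   0.426   1.300  1.00  0.00           C
ATOM      2  CB  PHE A   1      -0.270  -0.809   0.434  1.00  0.00           C
ATOM      3  CG  PHE A   1      -0.181  -0.430  -1.020  1.00  0.00           C
END
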