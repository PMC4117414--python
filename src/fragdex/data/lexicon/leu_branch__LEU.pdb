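REMARK   6 word template: Leucine branch
ATOM      1  CA  LEU A   1      -0.205   0.441  -0.467  1.00  0.00           C
ATOM      2  CB  LEU A   1       0.221  -0.583   0.585  1.00  0.00           C
ATOM      3  CG  LEU A   1      -0.170  -0.079   1.976  1.00  0.00           C
ATOM      4  CD1 LEU A   1       0.256  -1.104   3.029  1.00  0.00           C
ATOM      5  CD2 LEU A   1       0.526   1.254   2.250  1.00  0.00           C
END
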