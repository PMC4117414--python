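REMARK   6 word template: Indole ring
ATOM      1  CG  TRP A   1       0.650  -0.526  -0.225  1.00  0.00           C
ATOM      2  CD1 TRP A   1       1.928  -0.418  -0.622  1.00  0.00           C
ATOM      3  CD2 TRP A   1      -0.186  -0.256  -1.396  1.00  0.00           C
ATOM      4  NE1 TRP A   1       1.978  -0.095  -1.951  1.00  0.00           N
ATOM      5  CE2 TRP A   1       0.701   0.014  -2.454  1.00  0.00           C
ATOM      6  CE3 TRP A   1      -1.564  -0.210  -1.615  1.00  0.00           C
ATOM      7  CZ2 TRP A   1       0.190   0.314  -3.712  1.00  0.00           C
ATOM      8  CZ3 TRP A   1      -2.044   0.086  -2.859  1.00  0.00           C
ATOM      9  CH2 TRP A   1      -1.173   0.348  -3.907  1.00  0.00           C
END
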