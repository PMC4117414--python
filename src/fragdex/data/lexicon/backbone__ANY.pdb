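REMARK   6 word template: Backbone unit (N-CA-C-O)
ATOM      1  N   ANY A   1      -0.966   0.493   1.500  1.00  0.00           N
ATOM      2  CA  ANY A   1       0.257   0.418   0.692  1.00  0.00           C
ATOM      3  C   ANY A   1      -0.094   0.017  -0.716  1.00  0.00           C
ATOM      4  O   ANY A   1      -1.056  -0.682  -0.923  1.00  0.00           O
END
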