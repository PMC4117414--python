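REMARK   6 word template: Carboxylate
ATOM      1  CD  GLU A   1      -2.593  -0.187  -0.046  1.00  0.00           C
ATOM      2  OE1 GLU A   1      -2.485  -1.161  -0.753  1.00  0.00           O
ATOM      3  OE2 GLU A   1      -3.811   0.269   0.287  1.00  0.00           O
END
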