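REMARK SYNTHETIC fixture: coordinates are fabricated; the CRYST1 header
REMARK carries the published cell of the GLP-SAH binary complex entry
REMARK (orthorhombic P2(1)2(1)2(1)) for parser validation only.
CRYST1   74.520   95.860  102.120  90.00  90.00  90.00 P 21 21 21    4
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      13.034   6.686  -5.113  1.00 10.00           C
ATOM      4  O   ALA A   1      13.424   7.361  -4.157  1.00 10.00           O
ATOM      5  N   GLY A   2      13.800   6.441  -6.172  1.00 10.00           N
ATOM      6  CA  GLY A   2      15.153   6.966  -6.258  1.00 10.00           C
ATOM      7  C   GLY A   2      16.102   6.171  -5.370  1.00 10.00           C
ATOM      8  O   GLY A   2      17.132   6.690  -4.937  1.00 10.00           O
TER       9      GLY A   2
HETATM   10  O   HOH A 101       2.000   3.000   4.000  1.00 20.00           O
END
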