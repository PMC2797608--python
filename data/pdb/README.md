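# Deposited entries (user-supplied)

Place local copies of the deposited PDB entries here with lower-case
names (`2igq.pdb`, `2rfi.pdb`, `3hna.pdb`, `2o8j.pdb`, `2r3a.pdb`,
`2qpw.pdb`). The package performs no network access; the tests and
`scripts/acceptance.py` that validate published interface numbers
pick these files up automatically and state clearly when they are
absent.
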