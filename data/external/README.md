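# External sequences

Drop FASTA files here to enable the sequence targets that the repository
cannot redistribute:

- a record named `swc5` — the S. cerevisiae Swc5 protein (the first 79
  residues suffice), e.g. from UniProt or SGD;
- a record named `sv15` — the designed 50-residue E/K polyampholyte sv15
  from the Das–Pappu set.

`tests/test_acceptance.py` and `scripts/acceptance.py` pick up every
`*.fasta` in this directory automatically. Without these files the
corresponding tests skip and the acceptance report omits their keys.
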