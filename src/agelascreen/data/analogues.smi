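CN1C(=O)NC2C3n4c(Br)ccc4C(=O)NC3CC12O AA
CN1C(=O)NC2C3n4c(Br)c(Cl)cc4C(=O)NC3CC12O CAA
CN1C(=O)N(CC)C2C3n4c(Cl)ccc4C(=O)NC3CC12O CEAA
CN1C(=O)N(CC)C2C3n4c(Cl)c(Cl)cc4C(=O)NC3CC12O DCEAA
CN1C(=O)N(CC)C2C3n4c(Br)ccc4C(=O)NC3CC12O EAA
CN1C(=O)N(c2ccccc2)C3C4n5c(Br)ccc5C(=O)NC4CC13O PAA
CN1C(=O)NC2C3n4cccc4C(=O)NC3CC12O DeBAA
CN1C(=O)N(CC)C2C3n4cccc4C(=O)NC3CC12O DeBEAA
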