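# Structural-alert (mutagenicity toxicophore) library.
# General-purpose alert patterns in the style of the published mutagenicity
# toxicophore sets; editable. Format: label<TAB>SMARTS, '#' comments.
aromatic nitro	c[$([NX3](=O)=O),$([NX3+](=O)[O-])]
aromatic amine	c[NX3H2]
nitroso	[#6][NX2]=[OX1]
azo	[#6][NX2]=[NX2][#6]
aliphatic halide	[CX4][Cl,Br,I]
three-membered heterocycle	[#6]1[#6][#7,#8,#16]1
polycyclic aromatic system	c1ccc2c(c1)ccc1ccccc12
aromatic hydroxylamine	c[NX3][OX2H]
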