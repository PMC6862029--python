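# Reactive (electrophilic) group library; editable.
# Format: label<TAB>SMARTS, '#' comments.
acyl halide	[CX3](=[OX1])[F,Cl,Br,I]
aldehyde	[CX3H1]=[OX1]
epoxide/aziridine	[#6]1[#6][#7,#8]1
Michael acceptor	[CX3]=[CX3][$([CX3]=[OX1]),$([SX4](=[OX1])=[OX1])]
anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])
isocyanate	[NX2]=[CX2]=[OX1]
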