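# 26 common functional groups, Daylight-style SMARTS; editable.
# The first twelve are the groups discussed explicitly in the frequency
# profiling; the remainder are standard Daylight example groups.
# Format: label<TAB>SMARTS, '#' comments.
amide	[NX3][CX3](=[OX1])
carbonyl	[CX3]=[OX1]
carbonyl with nitrogen	[OX1]=[CX3][NX3]
hydroxyl in alcohol	[#6X4][OX2H]
vinylic carbon	[$([CX3]=[CX3])]
hydrazone	[NX3][NX2]=[CX3]
phenol	[OX2H][cX3]
sulfide	[#6][SX2][#6]
primary amine	[NX3H2;!$([NX3H2][CX3]=[OX1])]
secondary amine	[NX3H1;!$([NX3H1][CX3]=[OX1])]([#6])[#6]
ether	[OD2]([#6])[#6]
arene	c1ccccc1
tertiary amine	[NX3H0;!$([NX3H0][CX3]=[OX1]);!$([NX3H0+])]([#6])([#6])[#6]
carboxylic acid	[CX3](=[OX1])[OX2H1]
ester	[CX3](=[OX1])[OX2H0][#6]
ketone	[#6][CX3](=[OX1])[#6]
aldehyde	[CX3H1]=[OX1]
nitrile	[NX1]#[CX2]
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]
sulfone	[$([SX4](=[OX1])(=[OX1])([#6])[#6])]
sulfonamide	[SX4](=[OX1])(=[OX1])[NX3]
halogen	[F,Cl,Br,I]
thiol	[SX2H]
urea	[NX3][CX3](=[OX1])[NX3]
carbamate	[NX3][CX3](=[OX1])[OX2][#6]
guanidine	[NX3][CX3](=[NX2,NX3+])[NX3]
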