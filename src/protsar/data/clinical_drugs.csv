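# Clinical-stage human 20S proteasome inhibitors (beta5/CT-L site).
# Structures transcribed from their published 2D depictions and verified
# against the published descriptor table (formula, MW, TPSA, HBD, rings,
# Ro5 violations). IC50s are literature biochemical CT-L values.
id,smiles,ic50_nM,source
bortezomib,CC(C)C[C@@H](NC(=O)[C@@H](Cc1ccccc1)NC(=O)c1cnccn1)B(O)O,7,boronate; marketed (MM/MCL)
carfilzomib,CC(C)C[C@@H](NC(=O)[C@H](CCc1ccccc1)NC(=O)CN1CCOCC1)C(=O)N[C@@H](Cc1ccccc1)C(=O)N[C@@H](CC(C)C)C(=O)[C@]1(C)CO1,6,epoxyketone; marketed (MM)
ixazomib,CC(C)C[C@@H](NC(=O)CNC(=O)c1cc(Cl)ccc1Cl)B(O)O,3.4,boronate; marketed (MM)
delanzomib,C[C@H](O)[C@@H](NC(=O)c1cccc(-c2ccccc2)n1)C(=O)N[C@@H](CC(C)C)B(O)O,3.8,boronate; clinical trials
marizomib,C[C@@]12OC(=O)[C@@]1(NC(=O)[C@@H]2CCCl)[C@@H](O)C1C=CCCC1,3.5,beta-lactone; clinical trials
oprozomib,COC[C@@H](NC(=O)[C@@H](Cc1ccccc1)NC(=O)[C@@H](COC)NC(=O)c1csc(C)n1)C(=O)[C@@]1(C)CO1,36,epoxyketone; clinical trials
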