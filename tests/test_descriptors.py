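"""The 21-descriptor panel: individual operations and panel invariants."""

import numpy as np
import pytest
from rdkit import Chem

from protsar.chemio import parse_structure
from protsar.descriptors import (
    PANEL_FIELDS,
    DescriptorPanel,
    SmartsLibrary,
    atom_count,
    bond_census,
    compute_panel,
    count_hb,
    count_misc,
    flag_matches,
    functional_group_library,
    logp,
    logs,
    molar_refractivity,
    molecular_weight,
    reactive_library,
    rotatable_bonds,
    toxicophore_library,
    tpsa,
)


def mol(smiles: str):
    return parse_structure(smiles)


class TestSimpleDescriptors:
    def test_methane_panel_corner(self):
        v = compute_panel(mol("C"))
        assert v.a_count == 5
        assert v.MW == pytest.approx(16.0, abs=0.05)
        assert v.TPSA == 0.0
        assert v.rings == 0
        assert v.mutagenic == 0 and v.reactive == 0

    @pytest.mark.parametrize(
        "smiles,mw", [("c1ccccc1", 78.1), ("C", 16.0), ("O", 18.0)]
    )
    def test_molecular_weight_small(self, smiles, mw):
        assert molecular_weight(mol(smiles)) == pytest.approx(mw, abs=0.05)

    def test_benzene_tpsa_zero(self):
        assert tpsa(mol("c1ccccc1")) == 0.0

    def test_methane_logp_hand_sum(self):
        # Wildman-Crippen: C(sp3, no hetero) 0.1441 + 4 x H 0.1230
        assert logp(mol("C")) == pytest.approx(0.6361, abs=0.01)

    def test_benzene_mr_hand_sum(self):
        # 6 aromatic C (3.509) + 6 H (1.057) from the published table
        assert molar_refractivity(mol("c1ccccc1")) == pytest.approx(26.4, abs=0.1)

    def test_logs_decreases_with_lipophilic_size(self):
        assert logs(mol("CCCCCCCCCC")) < logs(mol("CCO"))


class TestHydrogenBonding:
    def test_water_lipinski(self):
        assert count_hb(mol("O"), "lipinski") == (1, 2)

    def test_water_intrinsic(self):
        assert count_hb(mol("O"), "intrinsic") == (1, 1)

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            count_hb(mol("O"), "nonsense")

    def test_drug_hbd_values(self, drug_panel):
        # donors on N/O: 2 amide N-H + 2 boronic O-H for the boronates
        expected = {
            "bortezomib": 4, "carfilzomib": 4, "ixazomib": 4,
            "delanzomib": 5, "marizomib": 2, "oprozomib": 3,
        }
        for name, hbd in expected.items():
            assert drug_panel.loc[name, "HBD"] == hbd

    def test_carfilzomib_lipinski_hba_is_n_plus_o(self, drug_by_id):
        # C40H57N5O7 -> 5 N + 7 O
        hba, _ = count_hb(drug_by_id["carfilzomib"].get_mol(), "lipinski")
        assert hba == 12

    def test_drug_intrinsic_hba_values(self, drug_panel):
        expected = {
            "bortezomib": 6, "carfilzomib": 8, "ixazomib": 4,
            "delanzomib": 6, "marizomib": 3, "oprozomib": 8,
        }
        for name, hba in expected.items():
            assert drug_panel.loc[name, "HBA"] == hba


class TestBonds:
    @pytest.mark.parametrize(
        "smiles,census",
        [
            ("c1ccccc1", (0, 0, 0, 6)),  # ring bonds all aromatic
            ("C=C", (0, 1, 0, 0)),
            ("CNC(C)=O", (3, 1, 0, 0)),  # N-methylacetamide by hand
            ("C#N", (0, 0, 1, 0)),
        ],
    )
    def test_bond_census(self, smiles, census):
        assert bond_census(mol(smiles)) == census

    def test_census_categories_sum_to_bond_total(self, synthetic_dataset):
        records, _ = synthetic_dataset
        for rec in records[:40]:
            m = rec.get_mol()
            assert sum(bond_census(m)) == m.GetNumBonds()

    @pytest.mark.parametrize(
        "smiles,strict,moe",
        [
            ("CC", (0, 0), (0, 0)),        # terminal atoms only
            ("CCCC", (1, 1), (1, 1)),      # n-butane central bond
            ("CNC(C)=O", (0, 0), (1, 0)),  # amide excluded only when strict
        ],
    )
    def test_rotatable_conventions(self, smiles, strict, moe):
        assert rotatable_bonds(mol(smiles), "strict") == strict
        assert rotatable_bonds(mol(smiles), "moe") == moe

    def test_drug_rotn_reference_values(self, drug_panel):
        expected = {
            "bortezomib": 11, "carfilzomib": 24, "ixazomib": 9,
            "delanzomib": 11, "marizomib": 4, "oprozomib": 17,
        }
        for name, rotn in expected.items():
            assert drug_panel.loc[name, "b_RotN"] == rotn


class TestMisc:
    def test_cyclohexane(self):
        a_hyd, rings, chiral, _, _ = count_misc(mol("C1CCCCC1"))
        assert (rings, chiral) == (1, 0)
        assert a_hyd == 6

    def test_drug_ring_counts(self, drug_panel):
        expected = {"bortezomib": 2, "carfilzomib": 4, "ixazomib": 1,
                    "delanzomib": 2, "marizomib": 3, "oprozomib": 3}
        for name, rings in expected.items():
            assert drug_panel.loc[name, "rings"] == rings


class TestSmartsFlags:
    def test_methane_matches_nothing(self):
        for lib in (toxicophore_library(), reactive_library()):
            assert flag_matches(mol("C"), lib) == []

    def test_carfilzomib_epoxide_is_alert(self, drug_by_id):
        m = drug_by_id["carfilzomib"].get_mol()
        assert "three-membered heterocycle" in flag_matches(m, toxicophore_library())
        assert "epoxide/aziridine" in flag_matches(m, reactive_library())

    def test_nitrobenzene_aromatic_nitro(self):
        labels = flag_matches(mol("O=[N+]([O-])c1ccccc1"), toxicophore_library())
        assert "aromatic nitro" in labels

    def test_functional_group_library_has_26_unique_groups(self):
        lib = functional_group_library()
        assert len(lib) == 26
        assert len(set(lib.labels)) == 26

    def test_bad_pattern_rejected_with_label(self):
        with pytest.raises(ValueError, match="broken"):
            SmartsLibrary("lib", [("broken", "[[")])

    def test_duplicate_label_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SmartsLibrary("lib", [("a", "C"), ("a", "N")])


class TestPanelInvariants:
    def test_panel_matches_individual_operations(self, drug_by_id):
        m = drug_by_id["bortezomib"].get_mol()
        v = compute_panel(m)
        assert v.a_count == atom_count(m)
        assert v.MW == molecular_weight(m)
        assert v.TPSA == tpsa(m)
        assert (v.b_single, v.b_double, v.b_triple, v.b_aro) == bond_census(m)
        assert (v.b_RotN, v.b_1RotN) == rotatable_bonds(m, "moe")
        assert v.logP_ow == logp(m)
        assert v.logS == logs(m)
        assert v.MR == molar_refractivity(m)
        a_hyd, rings, chiral, hba, hbd = count_misc(m)
        assert (v.a_hyd, v.rings, v.chiral, v.HBA, v.HBD) == (
            a_hyd, rings, chiral, hba, hbd
        )

    def test_atom_order_permutation_invariance(self, drug_records, rng):
        for rec in drug_records:
            m = rec.get_mol()
            perm = rng.permutation(m.GetNumAtoms()).tolist()
            shuffled = Chem.RenumberAtoms(m, perm)
            got = compute_panel(shuffled).as_dict()
            want = compute_panel(m).as_dict()
            assert got == pytest.approx(want, abs=1e-9)  # float sum order

    def test_tpsa_additivity_on_disconnected_union(self):
        # evaluated before fragment selection, so build the raw mol directly
        a, b = "CC(=O)O", "c1ccncc1O"
        union = Chem.MolFromSmiles(f"{a}.{b}")
        assert Chem.Descriptors.TPSA(union) == pytest.approx(
            tpsa(mol(a)) + tpsa(mol(b)), abs=1e-9
        )

    def test_mw_strictly_increases_with_heavy_atom(self):
        chains = ["C", "CC", "CCO", "CCOC", "c1ccccc1", "c1ccccc1C"]
        grown = ["CC", "CCC", "CCOC", "CCOCC", "c1ccccc1C", "c1ccccc1CC"]
        for small, big in zip(chains, grown):
            assert molecular_weight(mol(big)) > molecular_weight(mol(small))

    def test_lip_druglike_iff_at_most_one_violation(self, synthetic_dataset):
        _, panel = synthetic_dataset
        assert (panel["lip_druglike"] == (panel["lip_violation"] <= 1)).all()

    def test_counts_non_negative(self, synthetic_dataset):
        _, panel = synthetic_dataset
        count_cols = [c for c in PANEL_FIELDS if c not in
                      ("MW", "logP_ow", "logS", "TPSA", "MR", "lip_druglike")]
        assert (panel[count_cols] >= 0).all().all()

    def test_transformer_sklearn_contract(self, drug_records):
        est = DescriptorPanel()
        params = est.get_params()
        assert "include_auxiliary" in params
        out = est.fit(drug_records).transform(drug_records)
        assert list(out.columns) == est.get_feature_names_out()
        assert out.shape == (6, 23)
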