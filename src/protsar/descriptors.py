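"""The 21-descriptor panel used throughout the SAR analyses.

Panel (in canonical order, which also fixes decision-tree tie-breaking):

``a_count``   atoms including hydrogens
``a_hyd``     hydrophobic atoms (carbons with no N/O/S neighbour, plus halogens)
``HBA``       hydrogen-bond acceptor atoms (intrinsic/pharmacophore convention)
``HBD``       hydrogen-bond donor atoms (N/O bearing >=1 H)
``b_aro``     aromatic bonds
``b_single``  non-aromatic single bonds (heavy-atom graph)
``b_double``  double bonds
``b_triple``  triple bonds
``b_RotN``    rotatable bonds (MOE convention: non-ring single bonds between
              non-terminal heavy atoms, amide C-N included)
``b_1RotN``   rotatable single bonds: the subset of b_RotN whose flanking
              bonds are all single
``rings``     SSSR ring count
``chiral``    assigned or assignable tetrahedral stereocenters
``MW``        molecular weight, g/mol (average atomic masses, H included)
``logP_ow``   Wildman-Crippen octanol/water partition estimate
``logS``      ESOL aqueous solubility estimate (log mol/L)
``TPSA``      Ertl topological polar surface area, A^2 (N/O contributions)
``MR``        Crippen molar refractivity, cm^3/mol
``lip_druglike``  Lipinski drug-likeness flag (<=1 Ro5 violation)
``lip_violation`` number of Ro5 violations
``mutagenic`` toxicophore (structural-alert) matches
``reactive``  reactive-group matches

Two hydrogen-bond conventions coexist.  The *intrinsic* convention feeds the
panel's HBA/HBD and reproduces vendor-style pharmacophore counts: acceptors
are N/O with an available lone pair, excluding amide and sulfonamide
nitrogens, pyrrole-type aromatic N-H, and bridging ester oxygens; donors are
N/O atoms bearing at least one hydrogen.  The *lipinski* convention counts
N+O for acceptors and the total number of N-H/O-H hydrogens for donors, and
feeds the Ro5 violation count.  The auxiliary Lipinski counts are carried on
the descriptor vector (``hba_lipinski``/``hbd_lipinski``) next to the 21
canonical fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

from .chemio import parse_structure

logger = logging.getLogger(__name__)

__all__ = [
    "PANEL_FIELDS",
    "DescriptorVector",
    "SmartsLibrary",
    "DescriptorPanel",
    "compute_panel",
    "panel_frame",
    "atom_count",
    "molecular_weight",
    "tpsa",
    "count_hb",
    "bond_census",
    "rotatable_bonds",
    "logp",
    "logs",
    "molar_refractivity",
    "count_misc",
    "flag_matches",
    "toxicophore_library",
    "reactive_library",
    "functional_group_library",
]

#: canonical panel order; also the tie-break order for tree splits
PANEL_FIELDS = (
    "a_count", "a_hyd", "HBA", "HBD", "b_aro", "b_single", "b_double",
    "b_triple", "b_RotN", "b_1RotN", "rings", "chiral", "MW", "logP_ow",
    "logS", "TPSA", "MR", "lip_druglike", "lip_violation", "mutagenic",
    "reactive",
)


@dataclass
class DescriptorVector:
    """The 21 panel values for one molecule, plus auxiliary Lipinski counts."""

    a_count: int
    a_hyd: int
    HBA: int
    HBD: int
    b_aro: int
    b_single: int
    b_double: int
    b_triple: int
    b_RotN: int
    b_1RotN: int
    rings: int
    chiral: int
    MW: float
    logP_ow: float
    logS: float
    TPSA: float
    MR: float
    lip_druglike: bool
    lip_violation: int
    mutagenic: int
    reactive: int
    # auxiliary (not part of the 21-descriptor panel)
    hba_lipinski: int = 0
    hbd_lipinski: int = 0

    def as_dict(self, panel_only: bool = False) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclass_fields(self)}
        if panel_only:
            d = {k: d[k] for k in PANEL_FIELDS}
        return d

    def __getitem__(self, key: str):
        return getattr(self, key)


class SmartsLibrary:
    """A named list of (label, SMARTS) patterns, compiled at load time.

    File format: one ``label<TAB>pattern`` per line; lines starting with
    ``#`` are comments (SMARTS themselves may contain ``#``).  A pattern
    that fails to compile raises ``ValueError`` naming its label.
    """

    def __init__(self, name: str, entries: Iterable[tuple[str, str]]):
        self.name = name
        self.entries: list[tuple[str, str]] = []
        self._compiled: list[tuple[str, Chem.Mol]] = []
        seen: set[str] = set()
        for label, smarts in entries:
            if label in seen:
                raise ValueError(f"{name}: duplicate label {label!r}")
            seen.add(label)
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"{name}: SMARTS for {label!r} does not compile: {smarts!r}")
            self.entries.append((label, smarts))
            self._compiled.append((label, patt))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.entries]

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "SmartsLibrary":
        path = Path(path)
        entries = []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'label<TAB>pattern'")
            entries.append((parts[0].strip(), parts[1].strip()))
        return cls(name or path.stem, entries)

    def matches(self, mol: Chem.Mol) -> list[str]:
        """Labels whose pattern has at least one substructure embedding."""
        return [
            label for label, patt in self._compiled if mol.HasSubstructMatch(patt)
        ]


def _packaged_library(filename: str) -> SmartsLibrary:
    ref = resources.files("protsar.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return SmartsLibrary.from_file(path)


_LIB_CACHE: dict[str, SmartsLibrary] = {}


def toxicophore_library() -> SmartsLibrary:
    """Default structural-alert (mutagenicity toxicophore) library."""
    if "tox" not in _LIB_CACHE:
        _LIB_CACHE["tox"] = _packaged_library("toxicophores.smarts")
    return _LIB_CACHE["tox"]


def reactive_library() -> SmartsLibrary:
    """Default electrophilic/reactive-group library."""
    if "react" not in _LIB_CACHE:
        _LIB_CACHE["react"] = _packaged_library("reactive_groups.smarts")
    return _LIB_CACHE["react"]


def functional_group_library() -> SmartsLibrary:
    """Default 26-entry functional-group library (Daylight-style SMARTS)."""
    if "fg" not in _LIB_CACHE:
        _LIB_CACHE["fg"] = _packaged_library("functional_groups.smarts")
    return _LIB_CACHE["fg"]


# ---------------------------------------------------------------------------
# individual descriptor operations
# ---------------------------------------------------------------------------

def _as_mol(mol: Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, str):
        return parse_structure(mol)
    return mol


def atom_count(mol: Chem.Mol) -> int:
    """Number of atoms including hydrogens (vendor convention)."""
    mol = _as_mol(mol)
    return mol.GetNumAtoms() + sum(a.GetTotalNumHs() for a in mol.GetAtoms())


def molecular_weight(mol: Chem.Mol) -> float:
    """Average-atomic-mass molecular weight in g/mol, hydrogens included."""
    return RDDescriptors.MolWt(_as_mol(mol))


def tpsa(mol: Chem.Mol) -> float:
    """Ertl fragment-contribution topological polar surface area (A^2)."""
    return RDDescriptors.TPSA(_as_mol(mol))


def _is_carbonyl_like_carbon(atom: Chem.Atom) -> bool:
    """C doubly bonded to O (carbonyl carbon), used by the intrinsic rules."""
    if atom.GetSymbol() != "C":
        return False
    for bond in atom.GetBonds():
        if bond.GetBondTypeAsDouble() == 2.0 and bond.GetOtherAtom(atom).GetSymbol() == "O":
            return True
    return False


def count_hb(mol: Chem.Mol, convention: str = "intrinsic") -> tuple[int, int]:
    """(HBA, HBD) under the ``intrinsic`` or ``lipinski`` convention.

    ``lipinski``: HBA = N+O atom count; HBD = total hydrogens attached to
    N/O.  ``intrinsic``: acceptor atoms are N/O with a lone pair, excluding
    amide/sulfonamide N, pyrrole-type aromatic N-H, and bridging ester O;
    donor atoms are N/O bearing >=1 hydrogen.
    """
    mol = _as_mol(mol)
    if convention == "lipinski":
        hba = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
        hbd = sum(
            a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O")
        )
        return hba, hbd
    if convention != "intrinsic":
        raise ValueError(f"unknown H-bond convention {convention!r}")
    hba = 0
    hbd = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        if atom.GetTotalNumHs() > 0:
            hbd += 1
        if sym == "N":
            if any(_is_carbonyl_like_carbon(nb) for nb in atom.GetNeighbors()):
                continue  # amide-type N: lone pair delocalized
            if any(nb.GetSymbol() == "S" for nb in atom.GetNeighbors()):
                continue  # sulfonamide-type N
            if atom.GetIsAromatic() and atom.GetTotalNumHs() > 0:
                continue  # pyrrole-type N-H
            hba += 1
        else:
            neighbors = atom.GetNeighbors()
            if len(neighbors) == 2 and any(
                _is_carbonyl_like_carbon(nb) for nb in neighbors
            ):
                continue  # bridging ester/anhydride O
            hba += 1
    return hba, hbd


def bond_census(mol: Chem.Mol) -> tuple[int, int, int, int]:
    """(b_single, b_double, b_triple, b_aro) over the heavy-atom graph.

    Every bond belongs to exactly one category; aromatic bonds are neither
    single nor double.
    """
    mol = _as_mol(mol)
    single = double = triple = aro = 0
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        if bt == Chem.BondType.AROMATIC:
            aro += 1
        elif bt == Chem.BondType.SINGLE:
            single += 1
        elif bt == Chem.BondType.DOUBLE:
            double += 1
        elif bt == Chem.BondType.TRIPLE:
            triple += 1
        else:  # dative/other orders do not occur in standardized input
            logger.warning("uncategorized bond type %s counted as single", bt)
            single += 1
    return single, double, triple, aro


def _is_amide_bond(bond: Chem.Bond) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c_atom, n_atom in ((a, b), (b, a)):
        if c_atom.GetSymbol() == "C" and n_atom.GetSymbol() == "N":
            if _is_carbonyl_like_carbon(c_atom):
                return True
    return False


def rotatable_bonds(mol: Chem.Mol, convention: str = "moe") -> tuple[int, int]:
    """(b_RotN, b_1RotN).

    A bond is rotatable when it is a non-ring single bond whose two atoms
    each have at least two heavy neighbours.  The default ``moe`` convention
    counts amide C-N bonds (this is the convention the reference descriptor
    tables follow); ``strict`` excludes them.  ``b_1RotN`` is the subset of
    rotatable bonds all of whose flanking bonds are themselves single.
    """
    if convention not in ("moe", "strict"):
        raise ValueError(f"unknown rotatable-bond convention {convention!r}")
    mol = _as_mol(mol)
    rotn = rot1 = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:
            continue  # terminal heavy atom
        if convention == "strict" and _is_amide_bond(bond):
            continue
        rotn += 1
        flanking_single = True
        for atom in (a, b):
            for other in atom.GetBonds():
                if other.GetIdx() == bond.GetIdx():
                    continue
                if other.GetBondType() != Chem.BondType.SINGLE:
                    flanking_single = False
        if flanking_single:
            rot1 += 1
    return rotn, rot1


def logp(mol: Chem.Mol) -> float:
    """Wildman-Crippen atomic-contribution logP(o/w)."""
    return Crippen.MolLogP(_as_mol(mol))


def logs(mol: Chem.Mol) -> float:
    """ESOL aqueous solubility estimate, log10 mol/L.

    logS = 0.16 - 0.63 logP - 0.0062 MW + 0.066 RB - 0.74 AP, with RB the
    strict rotatable-bond count and AP the aromatic heavy-atom proportion.
    """
    mol = _as_mol(mol)
    mw = molecular_weight(mol)
    clogp = logp(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def molar_refractivity(mol: Chem.Mol) -> float:
    """Crippen atomic-contribution molar refractivity, cm^3/mol."""
    return Crippen.MolMR(_as_mol(mol))


def count_misc(mol: Chem.Mol) -> tuple[int, int, int, int, int]:
    """(a_hyd, rings, chiral, HBA_intrinsic, HBD_intrinsic).

    ``a_hyd`` approximates vendor hydrophobic-atom typing: carbons with no
    N/O/S neighbour, plus halogens.  ``rings`` is the SSSR count; ``chiral``
    counts assigned plus assignable tetrahedral stereocenters.
    """
    mol = _as_mol(mol)
    a_hyd = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "C":
            if not any(nb.GetSymbol() in ("N", "O", "S") for nb in atom.GetNeighbors()):
                a_hyd += 1
        elif sym in ("F", "Cl", "Br", "I"):
            a_hyd += 1
    rings = rdMolDescriptors.CalcNumRings(mol)
    chiral = len(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )
    hba, hbd = count_hb(mol, "intrinsic")
    return a_hyd, rings, chiral, hba, hbd


def flag_matches(mol: Chem.Mol, library: SmartsLibrary) -> list[str]:
    """Unique labels of library patterns with >=1 embedding in ``mol``."""
    return library.matches(_as_mol(mol))


def _lipinski_violations(mw: float, clogp: float, hba_lip: int, hbd_lip: int) -> int:
    return sum((mw > 500.0, clogp > 5.0, hba_lip > 10, hbd_lip > 5))


def compute_panel(
    mol: Chem.Mol | str,
    toxicophores: SmartsLibrary | None = None,
    reactives: SmartsLibrary | None = None,
) -> DescriptorVector:
    """Compute the full 21-descriptor panel for one standardized molecule."""
    mol = _as_mol(mol)
    a_hyd, rings, chiral, hba, hbd = count_misc(mol)
    b_single, b_double, b_triple, b_aro = bond_census(mol)
    b_rotn, b_1rotn = rotatable_bonds(mol, "moe")
    mw = molecular_weight(mol)
    clogp = logp(mol)
    hba_lip, hbd_lip = count_hb(mol, "lipinski")
    violations = _lipinski_violations(mw, clogp, hba_lip, hbd_lip)
    tox = toxicophores if toxicophores is not None else toxicophore_library()
    react = reactives if reactives is not None else reactive_library()
    return DescriptorVector(
        a_count=atom_count(mol),
        a_hyd=a_hyd,
        HBA=hba,
        HBD=hbd,
        b_aro=b_aro,
        b_single=b_single,
        b_double=b_double,
        b_triple=b_triple,
        b_RotN=b_rotn,
        b_1RotN=b_1rotn,
        rings=rings,
        chiral=chiral,
        MW=mw,
        logP_ow=clogp,
        logS=logs(mol),
        TPSA=tpsa(mol),
        MR=molar_refractivity(mol),
        lip_druglike=violations <= 1,
        lip_violation=violations,
        mutagenic=len(flag_matches(mol, tox)),
        reactive=len(flag_matches(mol, react)),
        hba_lipinski=hba_lip,
        hbd_lipinski=hbd_lip,
    )


class DescriptorPanel(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: molecules -> 21-column descriptor matrix.

    Parameters
    ----------
    include_auxiliary
        Also emit the auxiliary Lipinski H-bond count columns
        (``hba_lipinski``, ``hbd_lipinski``) after the canonical 21.
    toxicophores, reactives
        Override the packaged SMARTS libraries.

    The transformer is stateless; ``fit`` only records feature names
    (``feature_names_out_``).
    """

    def __init__(
        self,
        include_auxiliary: bool = True,
        toxicophores: SmartsLibrary | None = None,
        reactives: SmartsLibrary | None = None,
    ):
        self.include_auxiliary = include_auxiliary
        self.toxicophores = toxicophores
        self.reactives = reactives

    def fit(self, X: Sequence, y=None) -> "DescriptorPanel":
        cols = list(PANEL_FIELDS)
        if self.include_auxiliary:
            cols += ["hba_lipinski", "hbd_lipinski"]
        self.feature_names_out_ = cols
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence) -> pd.DataFrame:
        """``X``: sequence of RDKit molecules, SMILES strings or records."""
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        rows = []
        index = []
        for i, item in enumerate(X):
            mol = getattr(item, "get_mol", None)
            if callable(mol):  # CompoundRecord
                mol = item.get_mol()
                index.append(item.id)
            else:
                mol = _as_mol(item)
                index.append(i)
            vec = compute_panel(mol, self.toxicophores, self.reactives)
            rows.append(vec.as_dict(panel_only=not self.include_auxiliary))
        frame = pd.DataFrame(rows, index=index, columns=self.feature_names_out_)
        frame["lip_druglike"] = frame["lip_druglike"].astype(bool)
        return frame

    def get_feature_names_out(self, input_features=None):
        return list(self.feature_names_out_)


def panel_frame(items: Sequence, **kwargs) -> pd.DataFrame:
    """Thin functional wrapper over :class:`DescriptorPanel`."""
    return DescriptorPanel(**kwargs).fit(items).transform(items)
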