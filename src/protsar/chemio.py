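"""Compound I/O, structure standardization and IC50 activity-class binning.

The dataset model is a flat list of :class:`CompoundRecord` objects, each
carrying an identifier, a standardized SMILES, a beta5 (chymotrypsin-like
site) IC50 in nanomolar and the activity class derived from it:

====== ======================= =================
class  IC50 range (nM)         meaning
====== ======================= =================
A      IC50 <= 50              high activity
B      50  < IC50 <= 500       moderate activity
C      500 < IC50 <= 10000     low activity
D      10000 < IC50 <= 150000  marginal activity
====== ======================= =================

The four bins partition (0, 150000]; values outside that range are rejected.
The canonical datasets report 0.08 nM as the most potent measurement, so the
open lower edge never matters in practice.

Structures are standardized to 2D neutral form: the largest covalently
bonded fragment is kept (salt stripping), charges are neutralized where
chemically valid, and aromaticity is perceived.  All downstream descriptors
are topological, so no 3D preparation is performed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "StructureParseError",
    "DatasetError",
    "ACTIVITY_CLASSES",
    "CLASS_EDGES",
    "IC50_MAX_NM",
    "parse_structure",
    "canonical_smiles",
    "assign_activity_class",
    "read_dataset",
    "write_table",
    "records_to_frame",
]

ACTIVITY_CLASSES = ("A", "B", "C", "D")

#: right (inclusive) edges of the four activity bins, nM
CLASS_EDGES = {"A": 50.0, "B": 500.0, "C": 10_000.0, "D": 150_000.0}

IC50_MAX_NM = 150_000.0


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed into a molecule."""


class DatasetError(ValueError):
    """Raised for unusable dataset files (missing columns, no valid rows)."""


@dataclass
class CompoundRecord:
    """One compound: identifier, standardized structure, potency and class."""

    id: str
    smiles: str
    ic50_nM: float
    activity_class: str
    source: str = ""
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def get_mol(self) -> Chem.Mol:
        if self.mol is None:
            self.mol = parse_structure(self.smiles, record_id=self.id)
        return self.mol


_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()


def parse_structure(smiles: str, record_id: str | None = None) -> Chem.Mol:
    """Parse a SMILES string into a standardized RDKit molecule.

    Standardization keeps the largest covalently bonded fragment (declared
    salt-stripping policy), neutralizes charges where chemically valid and
    perceives aromaticity.  The result is stable: parsing the canonical
    SMILES of the output reproduces the same canonical SMILES.

    Raises
    ------
    StructureParseError
        If the string is empty or does not describe a valid molecule; the
        message names ``record_id`` when given.
    """
    label = f" (id={record_id})" if record_id else ""
    if not smiles or not str(smiles).strip():
        raise StructureParseError(f"empty structure string{label}")
    mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        raise StructureParseError(f"unparseable structure {smiles!r}{label}")
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES for a (standardized) molecule."""
    return Chem.MolToSmiles(mol)


def assign_activity_class(ic50_nM: float) -> str:
    """Bin an IC50 (nM) into activity class A/B/C/D.

    Intervals are closed on the right and open on the left, exactly as the
    bin edges are printed; the four bins partition (0, 150000] with no gaps
    or overlaps.

    Raises
    ------
    ValueError
        If ``ic50_nM`` is not a finite value in (0, 150000].
    """
    x = float(ic50_nM)
    if not x > 0 or x != x:
        raise ValueError(f"IC50 must be positive, got {ic50_nM!r}")
    if x > IC50_MAX_NM:
        raise ValueError(f"IC50 {ic50_nM!r} nM exceeds the {IC50_MAX_NM:.0f} nM range")
    for cls in ACTIVITY_CLASSES:
        if x <= CLASS_EDGES[cls]:
            return cls
    raise AssertionError("unreachable: bins cover (0, 150000]")


def _coerce_ic50(raw) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.upper() in {"NA", "NAN", "NONE", "NULL"}:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _make_record(rid: str, smiles: str, raw_ic50, source: str) -> CompoundRecord | None:
    """Build one standardized, class-assigned record; None (logged) if unusable."""
    ic50 = _coerce_ic50(raw_ic50)
    if ic50 is None:
        logger.warning("skipping %s: missing/non-numeric IC50 %r", rid, raw_ic50)
        return None
    try:
        mol = parse_structure(smiles, record_id=rid)
    except StructureParseError as exc:
        logger.warning("skipping %s: %s", rid, exc)
        return None
    try:
        cls = assign_activity_class(ic50)
    except ValueError as exc:
        logger.warning("excluding %s: %s", rid, exc)
        return None
    return CompoundRecord(
        id=str(rid), smiles=canonical_smiles(mol), ic50_nM=ic50,
        activity_class=cls, source=source, mol=mol,
    )


def _dedupe(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Keep the first occurrence of each canonical structure; log the rest.

    Stereoisomers carry distinct canonical SMILES and are kept distinct.
    """
    seen: dict[str, str] = {}
    out: list[CompoundRecord] = []
    for rec in records:
        if rec.smiles in seen:
            logger.warning(
                "duplicate structure: %s same as %s (kept first, IC50 of the "
                "first occurrence retained)", rec.id, seen[rec.smiles],
            )
            continue
        seen[rec.smiles] = rec.id
        out.append(rec)
    return out


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    ic50_tag: str = "IC50_nM",
    deduplicate: bool = True,
) -> list[CompoundRecord]:
    """Read a compound activity table from CSV or SDF.

    CSV dialect: UTF-8 with a header row and columns ``id,smiles,ic50_nM``
    (optional ``source``).  SDF: the IC50 is read from the property tag
    ``ic50_tag`` and the identifier from ``id``/``_Name``.

    Rows with missing or non-numeric IC50, unparseable structures, or IC50
    outside (0, 150000] nM are skipped with a logged warning.  Duplicate
    canonical structures keep the first occurrence.

    Raises
    ------
    DatasetError
        If required columns are absent or no row yields a valid record.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    if fmt == "csv":
        records = _read_csv(path)
    elif fmt == "sdf":
        records = _read_sdf(path, ic50_tag)
    else:
        raise DatasetError(f"unknown format {fmt!r} (expected 'csv' or 'sdf')")
    if deduplicate:
        records = _dedupe(records)
    if not records:
        raise DatasetError(f"no valid records in {path}")
    return records


def _read_csv(path: Path) -> list[CompoundRecord]:
    frame = pd.read_csv(path, dtype=str, comment="#")
    required = {"id", "smiles", "ic50_nM"}
    missing = required - set(frame.columns)
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        rec = _make_record(
            row.id, row.smiles, row.ic50_nM, getattr(row, "source", "") or ""
        )
        if rec is not None:
            out.append(rec)
    return out


def _read_sdf(path: Path, ic50_tag: str) -> list[CompoundRecord]:
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping SDF entry %d: unparseable", i)
            continue
        rid = mol.GetProp("id") if mol.HasProp("id") else (
            mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf-{i}"
        )
        if not mol.HasProp(ic50_tag):
            logger.warning("skipping %s: no property %r", rid, ic50_tag)
            continue
        rec = _make_record(rid, Chem.MolToSmiles(mol), mol.GetProp(ic50_tag), "")
        if rec is not None:
            out.append(rec)
    return out


def write_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write records as the CSV dialect ``read_dataset`` accepts (round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "ic50_nM", "activity_class", "source"])
        for rec in records:
            writer.writerow(
                [rec.id, rec.smiles, repr(rec.ic50_nM), rec.activity_class, rec.source]
            )


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame (id, smiles, ic50_nM, activity_class, source)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "ic50_nM": [r.ic50_nM for r in records],
            "activity_class": [r.activity_class for r in records],
            "source": [r.source for r in records],
        }
    )
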