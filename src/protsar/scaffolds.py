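"""Murcko scaffolds, fingerprint similarity, scaffold overlap and
chemical-space quadrant density.

Scaffold analyses operate on unique Murcko scaffolds per class (the
scaffold of a compound is its ring systems plus connecting linkers; acyclic
compounds have an empty scaffold and are excluded from scaffold statistics
and reported separately).  Similarity uses Morgan circular fingerprints of
radius 2 folded to 1024 bits and the Tanimoto coefficient.  A
compound-level similarity mode is available via ``unique_scaffolds=False``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

__all__ = [
    "FP_RADIUS",
    "FP_BITS",
    "murcko",
    "murcko_smiles",
    "fingerprint",
    "tanimoto",
    "scaffold_table",
    "class_similarity_profile",
    "scaffold_overlap",
    "quadrant_density",
    "embed_descriptors",
    "activity_cliffs",
]

FP_RADIUS = 2
FP_BITS = 1024

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_BITS
)


def murcko(mol: Chem.Mol) -> Chem.Mol:
    """Murcko scaffold: ring systems plus linkers, side chains pruned.

    Exocyclic double-bonded atoms attached to rings/linkers are retained.
    Acyclic molecules yield an empty molecule.
    """
    return MurckoScaffold.GetScaffoldForMol(mol)


def murcko_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of the Murcko scaffold ('' for acyclic molecules)."""
    return Chem.MolToSmiles(murcko(mol))


def fingerprint(mol: Chem.Mol):
    """Morgan fingerprint (radius 2, 1024-bit) as an RDKit bit vector."""
    return _fp_generator.GetFingerprint(mol)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between two fingerprints.

    Two all-zero bit vectors (identical empty scaffolds) compare as 1.0,
    with a warning.
    """
    if fp_a.GetNumOnBits() == 0 and fp_b.GetNumOnBits() == 0:
        warnings.warn("Tanimoto of two empty bitsets defined as 1.0")
        return 1.0
    return float(DataStructs.TanimotoSimilarity(fp_a, fp_b))


def scaffold_table(records: Sequence) -> pd.DataFrame:
    """Unique-scaffold table: scaffold SMILES, class flags, member count.

    Acyclic compounds (empty scaffold) are collected under the row with an
    empty scaffold string; scaffold statistics downstream exclude it.
    """
    info: dict[str, dict] = {}
    for rec in records:
        scaf = murcko_smiles(rec.get_mol())
        entry = info.setdefault(
            scaf, {"scaffold": scaf, "member_ids": [], "classes": set()}
        )
        entry["member_ids"].append(rec.id)
        entry["classes"].add(rec.activity_class)
    rows = []
    for entry in info.values():
        row = {
            "scaffold": entry["scaffold"],
            "n_members": len(entry["member_ids"]),
            "member_ids": ";".join(entry["member_ids"]),
        }
        for cls in ("A", "B", "C", "D"):
            row[f"in_class_{cls}"] = cls in entry["classes"]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("n_members", ascending=False, ignore_index=True)


def _scaffold_fps_by_class(records, unique_scaffolds: bool):
    """Fingerprints grouped by class (unique scaffolds or all compounds)."""
    by_class: dict[str, list] = {}
    seen: dict[str, set] = {}
    n_acyclic = 0
    for rec in records:
        mol = rec.get_mol()
        scaf = murcko_smiles(mol)
        if not scaf:
            n_acyclic += 1
            continue
        cls = rec.activity_class
        if unique_scaffolds:
            if scaf in seen.setdefault(cls, set()):
                continue
            seen[cls].add(scaf)
            target = Chem.MolFromSmiles(scaf)
        else:
            target = mol
        by_class.setdefault(cls, []).append(fingerprint(target))
    if n_acyclic:
        logger.info("excluded %d acyclic compounds (empty scaffold)", n_acyclic)
    return by_class


def class_similarity_profile(
    records: Sequence,
    unique_scaffolds: bool = True,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> dict[tuple[str, str], dict]:
    """Tanimoto distributions for every (class, class) pair.

    For within-class pairs, self-comparisons are excluded.  Each entry holds
    the raw coefficient array, its quantiles and a 20-bin histogram over
    [0, 1].  Classes with fewer than two scaffolds skip their within-class
    profile with a warning.
    """
    by_class = _scaffold_fps_by_class(records, unique_scaffolds)
    classes = sorted(by_class)
    out: dict[tuple[str, str], dict] = {}
    for i, c1 in enumerate(classes):
        for c2 in classes[i:]:
            if c1 == c2:
                fps = by_class[c1]
                if len(fps) < 2:
                    logger.warning("class %s has <2 scaffolds; profile skipped", c1)
                    continue
                values = [
                    tanimoto(a, b) for a, b in itertools.combinations(fps, 2)
                ]
            else:
                values = [
                    tanimoto(a, b)
                    for a in by_class[c1]
                    for b in by_class[c2]
                ]
            arr = np.asarray(values, dtype=float)
            hist, edges = np.histogram(arr, bins=20, range=(0.0, 1.0))
            out[(c1, c2)] = {
                "values": arr,
                "n_pairs": arr.size,
                "quantiles": {q: float(np.quantile(arr, q)) for q in quantiles},
                "median": float(np.median(arr)),
                "histogram": hist,
                "bin_edges": edges,
            }
    return out


def scaffold_overlap(records: Sequence) -> dict:
    """Scaffold-sharing structure across classes (Venn counts).

    Returns ``exact``: for every nonempty subset S of the classes present,
    the number of unique scaffolds occurring in exactly the classes of S;
    and ``pairwise``: for each class pair, the total number of scaffolds
    present in both (regardless of other classes).  Empty scaffolds are
    excluded.
    """
    membership: dict[str, set] = {}
    for rec in records:
        scaf = murcko_smiles(rec.get_mol())
        if not scaf:
            continue
        membership.setdefault(scaf, set()).add(rec.activity_class)
    exact: dict[frozenset, int] = {}
    for classes in membership.values():
        key = frozenset(classes)
        exact[key] = exact.get(key, 0) + 1
    all_classes = sorted(set().union(*membership.values())) if membership else []
    pairwise: dict[tuple[str, str], int] = {}
    for c1, c2 in itertools.combinations(all_classes, 2):
        pairwise[(c1, c2)] = sum(
            1 for classes in membership.values() if c1 in classes and c2 in classes
        )
    return {
        "n_scaffolds": len(membership),
        "exact": exact,
        "pairwise": pairwise,
    }


def quadrant_density(
    coords: np.ndarray, labels: Sequence[str]
) -> pd.DataFrame:
    """Per-class percentage of points in each quadrant of a 2D embedding.

    Quadrants are defined by the coordinate-wise medians of the embedding
    (invariant to translation); points exactly on a median line go to the
    upper/right side.  Rows (classes) sum to 100%.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be n x 2")
    labels = np.asarray(labels)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels length must match coords")
    mx, my = np.median(coords[:, 0]), np.median(coords[:, 1])
    right = coords[:, 0] >= mx
    top = coords[:, 1] >= my
    quadrant = np.where(
        top & right, "top_right",
        np.where(top & ~right, "top_left",
                 np.where(~top & right, "bottom_right", "bottom_left")),
    )
    quads = ("top_right", "top_left", "bottom_left", "bottom_right")
    rows = {}
    for cls in sorted(set(labels)):
        mask = labels == cls
        n = mask.sum()
        rows[cls] = [100.0 * np.sum(quadrant[mask] == q) / n for q in quads]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(quads))


def embed_descriptors(
    panel: pd.DataFrame, seed: int = 0, perplexity: float | None = None
) -> np.ndarray:
    """Delegated 2D t-SNE embedding of the standardized descriptor matrix.

    The embedding is stochastic up to the fixed ``seed``; downstream
    statistics (quadrant density) are median-based and translation
    invariant.
    """
    from sklearn.manifold import TSNE
    from sklearn.preprocessing import StandardScaler

    X = panel.astype(float).to_numpy()
    X = StandardScaler().fit_transform(X)
    if perplexity is None:
        perplexity = min(30.0, max(5.0, (X.shape[0] - 1) / 4))
    tsne = TSNE(
        n_components=2, random_state=seed, init="pca", perplexity=perplexity
    )
    return tsne.fit_transform(X)


def activity_cliffs(records: Sequence, min_fold: float = 100.0) -> pd.DataFrame:
    """Cross-class compound pairs sharing a scaffold, with IC50 fold-change.

    Highlights scaffolds whose decoration drives large potency shifts (an
    activity cliff); ``min_fold`` filters to pairs with at least that
    IC50 ratio.
    """
    by_scaffold: dict[str, list] = {}
    for rec in records:
        scaf = murcko_smiles(rec.get_mol())
        if scaf:
            by_scaffold.setdefault(scaf, []).append(rec)
    rows = []
    for scaf, members in by_scaffold.items():
        for a, b in itertools.combinations(members, 2):
            if a.activity_class == b.activity_class:
                continue
            low, high = sorted((a, b), key=lambda r: r.ic50_nM)
            fold = high.ic50_nM / low.ic50_nM
            if fold >= min_fold:
                rows.append(
                    {
                        "scaffold": scaf,
                        "potent_id": low.id,
                        "potent_class": low.activity_class,
                        "potent_ic50_nM": low.ic50_nM,
                        "weak_id": high.id,
                        "weak_class": high.activity_class,
                        "weak_ic50_nM": high.ic50_nM,
                        "fold_change": fold,
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "scaffold", "potent_id", "potent_class", "potent_ic50_nM",
            "weak_id", "weak_class", "weak_ic50_nM", "fold_change",
        ],
    )
    return frame.sort_values("fold_change", ascending=False, ignore_index=True)


def write_cliffs_sdf(cliffs: pd.DataFrame, records: Sequence, path) -> None:
    """Export activity-cliff pairs as an SDF annotated with fold-changes."""
    by_id = {r.id: r for r in records}
    writer = Chem.SDWriter(str(path))
    try:
        for row in cliffs.itertuples(index=False):
            for role in ("potent", "weak"):
                rec = by_id[getattr(row, f"{role}_id")]
                mol = Chem.Mol(rec.get_mol())
                mol.SetProp("_Name", rec.id)
                mol.SetProp("scaffold", row.scaffold)
                mol.SetProp("role", role)
                mol.SetProp("IC50_nM", repr(rec.ic50_nM))
                mol.SetProp("fold_change", f"{row.fold_change:.1f}")
                writer.write(mol)
    finally:
        writer.close()
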