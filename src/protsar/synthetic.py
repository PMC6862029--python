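"""Seeded generator of peptidomimetic-like inhibitor datasets.

Real proteasome-inhibitor collections are dominated by short peptide-like
backbones: an N-terminal cap, one to several amino-acid-like residues with
aromatic or aliphatic side chains, and a C-terminal electrophilic warhead
(boronic acid, epoxyketone, vinyl sulfone, aldehyde or beta-lactone).  The
generator emits real structures of that shape so every pipeline stage —
parsing, descriptors, substructure flags, scaffolds, fingerprints — is
exercised end to end.

Activity is planted through a descriptor rule: compounds satisfying the
rule are potent, the rest are weak, with lognormal assay noise,

    log10 IC50 = 4.0 - 2.5 * [rule satisfied] + Normal(0, sigma).

With the default sigma of 0.5 a rule-satisfying compound lands in class A
with probability ~0.65 and in class B otherwise, while a non-satisfying
compound splits ~3:1 between classes C and D — so a backbone-length mix in
which ~64% of structures satisfy the default rule reproduces the
283:126:208:63 class balance of the reference 680-compound collection.
The default planted rule (HBD >= 3 AND b_double >= 4 AND a_count >= 60)
keys on backbone length, which the residue-count weights control.

Everything is driven by one ``numpy`` generator: identical config and seed
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemio import CompoundRecord, assign_activity_class, canonical_smiles, parse_structure
from .descriptors import DescriptorPanel, compute_panel

__all__ = [
    "GeneratorConfig",
    "WARHEADS",
    "SIDE_CHAINS",
    "CAPS",
    "build_peptidomimetic",
    "plant_activity",
    "generate_dataset",
]

#: C-terminal warhead fragments; each replaces the final residue's carbonyl.
#: The fragment is appended after "N[C@@H](<side>)".
WARHEADS: Mapping[str, str] = {
    "boronic acid": "B(O)O",
    "epoxyketone": "C(=O)[C@]1(C)CO1",
    "vinyl sulfone": "/C=C/S(C)(=O)=O",
    "aldehyde": "C=O",
    "beta-lactone": "C1OC(=O)C1",
}

#: side-chain fragments, written from the alpha-carbon attachment point
SIDE_CHAINS: tuple[str, ...] = (
    "C",              # alanine-like
    "C(C)C",          # valine-like
    "CC(C)C",         # leucine-like
    "Cc1ccccc1",      # phenylalanine-like
    "CCc1ccccc1",     # homophenylalanine-like
    "Cc1cccc2ccccc12",  # naphthylalanine-like
    "CC1CCCCC1",      # cyclohexylalanine-like
    "CO",             # serine-like
    "CCSC",           # methionine-like
    "Cc1ccc(F)cc1",   # 4-fluorophenylalanine-like
)

#: N-terminal caps; each string ends at the carbonyl carbon that acylates
#: the first residue's nitrogen.
CAPS: Mapping[str, str] = {
    "acetyl": "CC(=O)",
    "morpholinoacetyl": "O=C(CN1CCOCC1)",
    "benzoyl": "O=C(c1ccccc1)",
    "pyrazinoyl": "O=C(c1cnccn1)",
}

#: default planted activity rule over panel descriptors
DEFAULT_RULE: tuple[tuple[str, str, float], ...] = (
    ("HBD", ">=", 3),
    ("b_double", ">=", 4),
    ("a_count", ">=", 60),
)

_OPS = {
    "<=": lambda v, t: v <= t,
    "<": lambda v, t: v < t,
    ">=": lambda v, t: v >= t,
    ">": lambda v, t: v > t,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_compounds: int = 680
    #: residue-count distribution; weights chosen so ~64% of structures
    #: satisfy the default planted rule (see module docstring)
    residue_weights: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.35, 3: 0.08, 4: 0.21, 5: 0.19, 6: 0.17}
    )
    side_chains: Sequence[str] = SIDE_CHAINS
    warheads: Sequence[str] = tuple(WARHEADS)
    caps: Sequence[str] = tuple(CAPS)
    planted_rule: Sequence[tuple[str, str, float]] = DEFAULT_RULE
    sigma: float = 0.5  # lognormal assay noise, log10 units
    #: reference class balance (informational; A:B:C:D of the emulated set)
    class_proportions: tuple[float, ...] = (283 / 680, 126 / 680, 208 / 680, 63 / 680)
    seed: int = 0

    def __post_init__(self):
        total = float(sum(self.residue_weights.values()))
        if not np.isclose(total, 1.0):
            raise ValueError(f"residue weights must sum to 1, got {total}")
        if not np.isclose(sum(self.class_proportions), 1.0):
            raise ValueError("class proportions must sum to 1")
        if any(1 > r or r > 8 for r in self.residue_weights):
            raise ValueError("residue counts must lie in 1..8")


def build_peptidomimetic(
    n_residues: int,
    side_chains: Sequence[str],
    warhead: str = "boronic acid",
    cap: str = "acetyl",
    rng: np.random.Generator | int | None = None,
) -> str:
    """Assemble a linear peptidomimetic SMILES.

    ``side_chains`` is either one fragment per residue (length
    ``n_residues``) or a library to sample from with ``rng``.  The backbone
    carries ``n_residues`` amide bonds (cap included) and ends in the named
    warhead.  Output is canonical and deterministic for fixed inputs/seed.
    """
    if not 1 <= n_residues <= 8:
        raise ValueError("n_residues must lie in 1..8")
    if warhead not in WARHEADS:
        raise ValueError(f"unknown warhead {warhead!r}; expected one of {list(WARHEADS)}")
    cap_smiles = CAPS.get(cap, cap)  # allow a raw cap fragment
    if len(side_chains) == n_residues:
        chosen = list(side_chains)
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        chosen = [side_chains[int(i)] for i in rng.integers(0, len(side_chains), n_residues)]
    parts = [cap_smiles]
    for i, side in enumerate(chosen):
        tail = WARHEADS[warhead] if i == n_residues - 1 else "C(=O)"
        parts.append(f"N[C@@H]({side}){tail}")
    smiles = "".join(parts)
    return canonical_smiles(parse_structure(smiles))


def _rule_satisfied(desc, rule) -> bool:
    return all(_OPS[op](float(desc[name]), threshold) for name, op, threshold in rule)


def plant_activity(
    desc,
    rule: Sequence[tuple[str, str, float]] = DEFAULT_RULE,
    sigma: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Draw an IC50 (nM) from the planted-rule noise model.

    log10 IC50 = 4.0 - 2.5*[rule satisfied] + Normal(0, sigma), with the
    result clipped to [0.08, 150000] nM.  ``sigma=0`` gives the exact
    closed forms 10^1.5 (satisfied) and 10^4 (violated).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    log_ic50 = 4.0 - 2.5 * float(_rule_satisfied(desc, rule))
    if sigma > 0:
        log_ic50 += rng.normal(0.0, sigma)
    return float(np.clip(10.0 ** log_ic50, 0.08, 150_000.0))


def generate_dataset(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Generate a class-labeled synthetic dataset with its descriptor panel.

    Returns ``(records, panel)`` where ``panel`` is indexed by compound id.
    ``seed`` overrides ``config.seed``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = sorted(config.residue_weights)
    weights = np.array([config.residue_weights[c] for c in counts], dtype=float)
    weights = weights / weights.sum()

    records: list[CompoundRecord] = []
    rows = []
    panel = DescriptorPanel().fit([])
    for i in range(config.n_compounds):
        n_res = int(rng.choice(counts, p=weights))
        warhead = str(rng.choice(list(config.warheads)))
        cap = str(rng.choice(list(config.caps)))
        smiles = build_peptidomimetic(
            n_res, config.side_chains, warhead=warhead, cap=cap, rng=rng
        )
        mol = parse_structure(smiles)
        vec = compute_panel(mol)
        ic50 = plant_activity(vec, config.planted_rule, config.sigma, rng)
        rid = f"SYN-{i + 1:04d}"
        records.append(
            CompoundRecord(
                id=rid,
                smiles=smiles,
                ic50_nM=ic50,
                activity_class=assign_activity_class(ic50),
                source=f"synthetic: {n_res} residues, {warhead}, {cap} cap",
                mol=mol,
            )
        )
        rows.append(vec.as_dict())
    frame = pd.DataFrame(rows, index=[r.id for r in records], columns=panel.feature_names_out_)
    frame["lip_druglike"] = frame["lip_druglike"].astype(bool)
    return records, frame
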