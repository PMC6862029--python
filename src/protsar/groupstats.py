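"""Functional-group frequency profiling and enrichment statistics.

Frequencies are the percentage of compounds in each activity class with at
least one substructure match for a group.  A group's trend across classes is
classified from the Spearman correlation of its frequency vector against the
activity rank (A=4 ... D=1): |rho| >= 0.8 together with a frequency range of
at least 15 percentage points labels the group ``direct`` (more frequent in
more active classes) or ``inverse``; everything else is ``flat``.

Pairwise class contrasts use the two-sided Fisher exact test in its "at most
as probable" convention, with Benjamini-Hochberg adjustment applied within
the family of simultaneous tests of one profiling call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GroupProfile", "fisher_exact", "bh_adjust", "profile_groups", "classify_trend"]

#: activity rank used for trend classification (higher = more active)
CLASS_RANK = {"A": 4, "B": 3, "C": 2, "D": 1}

TREND_RHO_MIN = 0.8
TREND_RANGE_MIN = 15.0  # percentage points


@dataclass
class GroupProfile:
    """Per-class match frequencies and trend label for one functional group."""

    label: str
    frequencies: dict[str, float]  # class -> % of class members matching
    trend: str  # direct | inverse | flat
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums hypergeometric probabilities of all tables (margins fixed) at most
    as probable as the observed one.  A degenerate table with a zero margin
    has p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of non-negative integer counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def classify_trend(frequencies: dict[str, float]) -> str:
    """Label a frequency-vs-activity-rank profile direct/inverse/flat."""
    classes = [c for c in frequencies if c in CLASS_RANK]
    if len(classes) < 3:
        return "flat"
    freqs = np.array([frequencies[c] for c in classes], dtype=float)
    ranks = np.array([CLASS_RANK[c] for c in classes], dtype=float)
    if freqs.max() - freqs.min() < TREND_RANGE_MIN:
        return "flat"
    if np.all(freqs == freqs[0]):
        return "flat"
    rho = sps.spearmanr(ranks, freqs).statistic
    if np.isnan(rho) or abs(rho) < TREND_RHO_MIN:
        return "flat"
    return "direct" if rho > 0 else "inverse"


def profile_groups(
    records: Sequence,
    library=None,
    with_pairwise: bool = True,
) -> list[GroupProfile]:
    """Profile functional-group frequencies across activity classes.

    ``records`` are class-assigned compound records; ``library`` defaults to
    the packaged 26-group SMARTS library.  Returns one profile per group.
    Empty classes are flagged and excluded from that group's trend.
    """
    from .descriptors import functional_group_library

    if library is None:
        library = functional_group_library()

    classes = sorted({r.activity_class for r in records})
    by_class: dict[str, list] = {c: [] for c in classes}
    for rec in records:
        by_class[rec.activity_class].append(rec)

    # one substructure scan per compound, reused across groups
    match_sets = {}
    for rec in records:
        match_sets[rec.id] = set(library.matches(rec.get_mol()))

    profiles: list[GroupProfile] = []
    all_pairs: list[dict] = []
    for label in library.labels:
        freqs: dict[str, float] = {}
        counts: dict[str, tuple[int, int]] = {}
        for cls in classes:
            members = by_class[cls]
            if not members:
                logger.warning("class %s empty; frequency undefined for %r", cls, label)
                continue
            hits = sum(1 for rec in members if label in match_sets[rec.id])
            counts[cls] = (hits, len(members))
            freqs[cls] = 100.0 * hits / len(members)
        profile = GroupProfile(label=label, frequencies=freqs, trend=classify_trend(freqs))
        profiles.append(profile)
        if with_pairwise:
            present = [c for c in classes if c in counts]
            for i, c1 in enumerate(present):
                for c2 in present[i + 1:]:
                    h1, n1 = counts[c1]
                    h2, n2 = counts[c2]
                    all_pairs.append(
                        {
                            "group": label,
                            "class_1": c1,
                            "class_2": c2,
                            "p_value": fisher_exact([[h1, n1 - h1], [h2, n2 - h2]]),
                        }
                    )

    if with_pairwise and all_pairs:
        adjusted = bh_adjust([row["p_value"] for row in all_pairs])
        for row, p_adj in zip(all_pairs, adjusted):
            row["p_adj"] = p_adj
        pair_frame = pd.DataFrame(all_pairs)
        for profile in profiles:
            profile.pairwise = pair_frame[pair_frame["group"] == profile.label].reset_index(
                drop=True
            )
    return profiles


def profiles_to_frame(profiles: Sequence[GroupProfile]) -> pd.DataFrame:
    """Tidy (group, class, frequency, trend) table for export."""
    rows = []
    for p in profiles:
        for cls, freq in p.frequencies.items():
            rows.append(
                {"group": p.label, "activity_class": cls, "frequency": freq, "trend": p.trend}
            )
    return pd.DataFrame(rows)
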