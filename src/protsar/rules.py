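"""Drug-likeness rule engines and the high-activity guideline filter.

Six rule systems ship as configuration data (``data/rulesets.yaml``):
Lipinski's rule of five, Ghose, Veber (extended Ro5), Oprea's drug-like and
lead-like boxes, and the known-drug space (KDS).  Lipinski passes with up to
one violated bound; every other system requires all bounds simultaneously.

The "chemical spaces" coverage analysis uses three of these: drug-like
(Oprea), lead-like (Oprea lead-like) and known-drug (KDS).  Lipinski
membership is reported separately as ``lip_druglike`` — a compound can pass
the Ro5 yet sit outside all three spaces (bortezomib does exactly that, via
its rotatable-bond count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import groupstats

logger = logging.getLogger(__name__)

__all__ = [
    "Bound",
    "RuleSet",
    "RuleResult",
    "RuleReport",
    "GuidelineRule",
    "load_rulesets",
    "load_guideline_rules",
    "lipinski",
    "evaluate_spaces",
    "guideline_filter",
    "class_coverage",
    "SPACE_NAMES",
]

#: names of the three chemical spaces in the coverage analysis
SPACE_NAMES = ("drug_like", "lead_like", "known_drug")

_COMPARATORS = {
    "<=": lambda v, t: v <= t,
    "<": lambda v, t: v < t,
    ">=": lambda v, t: v >= t,
    ">": lambda v, t: v > t,
}


@dataclass(frozen=True)
class Bound:
    """An inclusive interval constraint on one descriptor."""

    descriptor: str
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"{self.descriptor}: lower {self.lower} > upper {self.upper}")

    def check(self, value: float) -> bool:
        if self.lower is not None and value < self.lower:
            return False
        if self.upper is not None and value > self.upper:
            return False
        return True

    def __str__(self) -> str:
        lo = "-inf" if self.lower is None else self.lower
        hi = "+inf" if self.upper is None else self.upper
        return f"{self.descriptor} in [{lo}; {hi}]"


@dataclass
class RuleSet:
    """A named set of descriptor bounds with a violation tolerance."""

    name: str
    bounds: list[Bound]
    violation_tolerance: int = 0
    skipped: list[str] = field(default_factory=list)

    def evaluate(self, desc: Mapping) -> "RuleResult":
        violated = [b for b in self.bounds if not b.check(_lookup(desc, b.descriptor))]
        return RuleResult(
            ruleset=self.name,
            passed=len(violated) <= self.violation_tolerance,
            violations=[str(b) for b in violated],
            n_violations=len(violated),
            skipped=list(self.skipped),
        )


@dataclass
class RuleResult:
    ruleset: str
    passed: bool
    violations: list[str]
    n_violations: int
    skipped: list[str] = field(default_factory=list)


@dataclass
class RuleReport:
    """Evaluation of one molecule against every configured rule system."""

    results: dict[str, RuleResult]
    spaces: dict[str, bool]
    lip_violation: int

    def passes(self, name: str) -> bool:
        return self.results[name].passed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ruleset": list(self.results),
                "passed": [r.passed for r in self.results.values()],
                "n_violations": [r.n_violations for r in self.results.values()],
                "violations": ["; ".join(r.violations) for r in self.results.values()],
            }
        )


@dataclass(frozen=True)
class GuidelineRule:
    """An ordered conjunction of (descriptor, comparator, threshold) clauses."""

    label: str
    clauses: tuple[tuple[str, str, float], ...]
    provenance: str = "decision-tree guideline"

    def satisfied(self, desc: Mapping) -> bool:
        return all(
            _COMPARATORS[op](_lookup(desc, name), threshold)
            for name, op, threshold in self.clauses
        )


def _lookup(desc: Mapping, name: str) -> float:
    """Fetch a descriptor by rule-config name from a vector/row/mapping."""
    key = "hba_lipinski" if name == "HBA_lipinski" else (
        "hbd_lipinski" if name == "HBD_lipinski" else name
    )
    try:
        return float(desc[key])
    except (KeyError, AttributeError, TypeError):
        pass
    try:
        return float(getattr(desc, key))
    except AttributeError:
        raise KeyError(f"rule references unknown descriptor {name!r}") from None


def _default_config_path(filename: str) -> Path:
    ref = resources.files("protsar.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return Path(path)


def load_rulesets(path: str | Path | None = None) -> tuple[dict[str, RuleSet], dict[str, str]]:
    """Load rule systems and the space->ruleset mapping from YAML config."""
    path = Path(path) if path is not None else _default_config_path("rulesets.yaml")
    raw = yaml.safe_load(path.read_text())
    rulesets: dict[str, RuleSet] = {}
    for name, spec in raw["rulesets"].items():
        bounds = [
            Bound(desc, *(None if v is None else float(v) for v in lohi))
            for desc, lohi in spec["bounds"].items()
        ]
        rulesets[name] = RuleSet(
            name=name,
            bounds=bounds,
            violation_tolerance=int(spec.get("violation_tolerance", 0)),
            skipped=list(spec.get("skipped", [])),
        )
    spaces = dict(raw.get("spaces", {}))
    for space, ruleset in spaces.items():
        if ruleset not in rulesets:
            raise ValueError(f"space {space!r} references unknown ruleset {ruleset!r}")
    return rulesets, spaces


def load_guideline_rules(path: str | Path | None = None) -> list[GuidelineRule]:
    """Load guideline rules (ordered conjunctions) from YAML config."""
    path = Path(path) if path is not None else _default_config_path("guideline_rules.yaml")
    raw = yaml.safe_load(path.read_text())
    rules = []
    for spec in raw["rules"]:
        clauses = []
        for name, op, threshold in spec["clauses"]:
            if op not in _COMPARATORS:
                raise ValueError(f"{spec['label']}: unknown comparator {op!r}")
            clauses.append((name, op, float(threshold)))
        rules.append(GuidelineRule(label=spec["label"], clauses=tuple(clauses)))
    return rules


def lipinski(desc: Mapping) -> tuple[bool, int]:
    """(druglike, violations) under the rule of five.

    Violations are counted over MW > 500, logP > 5, N+O > 10 and NH+OH > 5
    hydrogens; a compound stays drug-like with at most one violation.
    """
    violations = sum(
        (
            _lookup(desc, "MW") > 500.0,
            _lookup(desc, "logP_ow") > 5.0,
            _lookup(desc, "HBA_lipinski") > 10,
            _lookup(desc, "HBD_lipinski") > 5,
        )
    )
    return violations <= 1, violations


def evaluate_spaces(
    desc: Mapping, rulesets_path: str | Path | None = None
) -> RuleReport:
    """Evaluate one descriptor vector against every configured rule system."""
    rulesets, space_map = load_rulesets(rulesets_path)
    results = {name: rs.evaluate(desc) for name, rs in rulesets.items()}
    spaces = {space: results[rs].passed for space, rs in space_map.items()}
    _, lip_violations = lipinski(desc)
    return RuleReport(results=results, spaces=spaces, lip_violation=lip_violations)


def guideline_filter(
    desc: Mapping, rules: Sequence[GuidelineRule] | None = None
) -> tuple[bool, str | None]:
    """Apply the high-activity guideline; first satisfied rule wins.

    Returns ``(True, label)`` when any rule's conjunction holds and
    ``(False, None)`` otherwise.
    """
    if rules is None:
        rules = load_guideline_rules()
    for rule in rules:
        if rule.satisfied(desc):
            return True, rule.label
    return False, None


def class_coverage(
    records: Sequence,
    panels: pd.DataFrame,
    metric: str = "lip_druglike",
) -> pd.DataFrame:
    """Per-class proportion of a boolean panel metric, with pairwise stats.

    ``metric`` is ``lip_druglike`` (fraction passing the Ro5) or
    ``mutagenic`` (fraction with >=1 structural alert).  Returns a tidy
    frame of per-class proportions; pairwise two-sided Fisher tests with
    Benjamini-Hochberg adjustment (one family per call) are attached in
    ``frame.attrs['pairwise']``.
    """
    classes = sorted({r.activity_class for r in records})
    labels = pd.Series([r.activity_class for r in records], index=panels.index)
    if metric == "lip_druglike":
        flags = panels["lip_druglike"].astype(bool)
    elif metric == "mutagenic":
        flags = panels["mutagenic"] >= 1
    else:
        raise ValueError(f"unknown coverage metric {metric!r}")

    rows = []
    counts: dict[str, tuple[int, int]] = {}
    for cls in classes:
        mask = labels == cls
        n = int(mask.sum())
        hits = int(flags[mask].sum())
        counts[cls] = (hits, n)
        rows.append(
            {
                "activity_class": cls,
                "metric": metric,
                "n": n,
                "n_positive": hits,
                "proportion": hits / n if n else float("nan"),
            }
        )
        if n == 0:
            logger.warning("class %s is empty; proportion undefined", cls)

    pair_rows = []
    pvals = []
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            h1, n1 = counts[c1]
            h2, n2 = counts[c2]
            p = groupstats.fisher_exact([[h1, n1 - h1], [h2, n2 - h2]])
            pvals.append(p)
            pair_rows.append({"class_1": c1, "class_2": c2, "p_value": p})
    if pvals:
        adjusted = groupstats.bh_adjust(pvals)
        for row, p_adj in zip(pair_rows, adjusted):
            row["p_adj"] = p_adj

    frame = pd.DataFrame(rows)
    frame.attrs["pairwise"] = pd.DataFrame(pair_rows)
    return frame
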