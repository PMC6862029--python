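"""Stage orchestration: run analyses and write their artifacts.

Each stage reads a compound table (or the synthetic generator's output),
runs one slice of the analysis and writes plain-text artifacts into the
output directory:

``profile``    descriptor table (CSV) for every compound
``rules``      drug-likeness rule report + chemical-space coverage (CSV/JSON)
``scaffolds``  scaffold table, Venn counts, similarity summaries, cliffs
``tree``       fitted tree (JSON) + extracted decision rules (CSV/text)
``groups``     functional-group frequency profiles (CSV)
``simulate``   synthetic dataset (CSV, the dialect ``read_dataset`` accepts)
``report``     markdown summary assembled from prior stage outputs
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .chemio import CompoundRecord, read_dataset, records_to_frame, write_table
from .descriptors import DescriptorPanel
from .groupstats import profile_groups, profiles_to_frame
from .rules import class_coverage, evaluate_spaces, guideline_filter, load_guideline_rules
from .scaffolds import (
    activity_cliffs,
    class_similarity_profile,
    quadrant_density,
    embed_descriptors,
    scaffold_overlap,
    scaffold_table,
)
from .synthetic import GeneratorConfig, generate_dataset
from .tree import ActivityTree, extract_rules, rules_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_stage", "clinical_drugs_path"]


class StageError(RuntimeError):
    """A stage could not run (bad input or missing upstream artifact)."""


@dataclass
class PipelineConfig:
    """Paths and hyperparameters; the defaults reproduce the canonical
    analysis settings (bin edges, tree depth 7, min leaf 5, 1024-bit
    radius-2 fingerprints)."""

    input_path: Path | None = None
    out_dir: Path = Path("protsar_out")
    max_depth: int = 7
    min_samples_leaf: int = 5
    embedding_seed: int = 0
    seed: int = 0
    n_compounds: int = 680
    rulesets_path: Path | None = None
    guideline_path: Path | None = None
    target_class: str = "A"
    fmt: str = "csv"

    def outdir(self) -> Path:
        self.out_dir = Path(self.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        return self.out_dir


def clinical_drugs_path() -> Path:
    """Path to the packaged six-drug clinical fixture table."""
    ref = resources.files("protsar.data").joinpath("clinical_drugs.csv")
    with resources.as_file(ref) as path:
        return Path(path)


def _load_records(config: PipelineConfig) -> list[CompoundRecord]:
    path = config.input_path
    if path is None:
        raise StageError("no --input given and no synthetic dataset to fall back on")
    path = Path(path)
    if not path.exists():
        raise StageError(f"input {path} does not exist")
    return read_dataset(path)


def _panel_for(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    return DescriptorPanel().fit(records).transform(records)


def run_stage(stage: str, config: PipelineConfig) -> list[Path]:
    """Run one named stage; returns the artifact paths written."""
    runners = {
        "profile": _stage_profile,
        "rules": _stage_rules,
        "scaffolds": _stage_scaffolds,
        "tree": _stage_tree,
        "groups": _stage_groups,
        "simulate": _stage_simulate,
        "report": _stage_report,
    }
    if stage not in runners:
        raise StageError(f"unknown stage {stage!r}; expected one of {sorted(runners)}")
    out = config.outdir()
    logger.info("stage=%s version=%s seed=%d out=%s", stage, __version__, config.seed, out)
    artifacts = runners[stage](config)
    logger.info("stage=%s wrote %d artifact(s)", stage, len(artifacts))
    return artifacts


def _stage_profile(config: PipelineConfig) -> list[Path]:
    records = _load_records(config)
    panel = _panel_for(records)
    meta = records_to_frame(records).set_index("id")
    table = meta.join(panel)
    path = config.outdir() / "descriptor_table.csv"
    table.to_csv(path, index_label="id")
    logger.info("profiled %d compounds", len(records))
    return [path]


def _stage_rules(config: PipelineConfig) -> list[Path]:
    records = _load_records(config)
    panel = _panel_for(records)
    rows = []
    guideline = load_guideline_rules(config.guideline_path)
    for rec in records:
        desc = panel.loc[rec.id]
        report = evaluate_spaces(desc, config.rulesets_path)
        passed, fired = guideline_filter(desc, guideline)
        row = {"id": rec.id, "activity_class": rec.activity_class,
               "lip_violation": report.lip_violation}
        for name, res in report.results.items():
            row[f"pass_{name}"] = res.passed
        for space, ok in report.spaces.items():
            row[f"space_{space}"] = ok
        row["guideline_pass"] = passed
        row["guideline_rule"] = fired or "none"
        rows.append(row)
    frame = pd.DataFrame(rows)
    out = config.outdir()
    paths = [out / "rule_report.csv", out / "space_coverage.json"]
    frame.to_csv(paths[0], index=False)
    coverage = {}
    for metric in ("lip_druglike", "mutagenic"):
        cov = class_coverage(records, panel, metric=metric)
        coverage[metric] = {
            "proportions": dict(zip(cov["activity_class"], cov["proportion"])),
            "pairwise": cov.attrs["pairwise"].to_dict(orient="records"),
        }
    paths[1].write_text(json.dumps(coverage, indent=2))
    return paths


def _stage_scaffolds(config: PipelineConfig) -> list[Path]:
    records = _load_records(config)
    out = config.outdir()
    table = scaffold_table(records)
    overlap = scaffold_overlap(records)
    profile = class_similarity_profile(records)
    cliffs = activity_cliffs(records)
    panel = _panel_for(records)
    coords = embed_descriptors(panel[list(panel.columns[:21])], seed=config.embedding_seed)
    density = quadrant_density(coords, [r.activity_class for r in records])
    paths = []
    p = out / "scaffold_table.csv"; table.to_csv(p, index=False); paths.append(p)
    p = out / "scaffold_venn.json"
    p.write_text(json.dumps({
        "n_scaffolds": overlap["n_scaffolds"],
        "exact": {"+".join(sorted(k)): v for k, v in overlap["exact"].items()},
        "pairwise": {f"{a}+{b}": v for (a, b), v in overlap["pairwise"].items()},
    }, indent=2))
    paths.append(p)
    p = out / "similarity_summary.csv"
    pd.DataFrame(
        [
            {"class_1": c1, "class_2": c2, "n_pairs": d["n_pairs"],
             "median_tc": d["median"],
             **{f"q{int(q * 100):02d}": v for q, v in d["quantiles"].items()}}
            for (c1, c2), d in profile.items()
        ]
    ).to_csv(p, index=False)
    paths.append(p)
    p = out / "activity_cliffs.csv"; cliffs.to_csv(p, index=False); paths.append(p)
    p = out / "quadrant_density.csv"; density.to_csv(p, index_label="activity_class")
    paths.append(p)
    return paths


def _stage_tree(config: PipelineConfig) -> list[Path]:
    records = _load_records(config)
    panel = _panel_for(records)
    X = panel[list(panel.columns[:21])]
    y = [r.activity_class for r in records]
    est = ActivityTree(
        max_depth=config.max_depth, min_samples_leaf=config.min_samples_leaf
    ).fit(X, y)
    rules = extract_rules(est, config.target_class)
    out = config.outdir()
    paths = [out / "tree.json", out / "decision_rules.csv", out / "decision_rules.txt"]
    paths[0].write_text(est.to_json())
    rules_to_frame(rules).to_csv(paths[1], index=False)
    paths[2].write_text("\n".join(str(r) for r in rules) + "\n")
    logger.info("extracted %d class-%s rule(s)", len(rules), config.target_class)
    return paths


def _stage_groups(config: PipelineConfig) -> list[Path]:
    records = _load_records(config)
    profiles = profile_groups(records)
    out = config.outdir()
    paths = [out / "group_profiles.csv", out / "group_pairwise.csv"]
    profiles_to_frame(profiles).to_csv(paths[0], index=False)
    pd.concat(
        [p.pairwise for p in profiles if len(p.pairwise)], ignore_index=True
    ).to_csv(paths[1], index=False)
    return paths


def _stage_simulate(config: PipelineConfig) -> list[Path]:
    gen = GeneratorConfig(n_compounds=config.n_compounds, seed=config.seed)
    records, panel = generate_dataset(gen)
    out = config.outdir()
    paths = [out / "synthetic_dataset.csv", out / "synthetic_panel.csv"]
    write_table(records, paths[0])
    panel.to_csv(paths[1], index_label="id")
    counts = pd.Series([r.activity_class for r in records]).value_counts()
    logger.info("simulated %d compounds; class counts %s", len(records), counts.to_dict())
    return paths


_REPORT_INPUTS = {
    "descriptor_table.csv": "profile",
    "rule_report.csv": "rules",
    "decision_rules.csv": "tree",
    "group_profiles.csv": "groups",
}


def _stage_report(config: PipelineConfig) -> list[Path]:
    out = config.outdir()
    missing = [f"{name} (run '{stage}')" for name, stage in _REPORT_INPUTS.items()
               if not (out / name).exists()]
    if missing:
        raise StageError("report needs prior stage outputs; missing: " + ", ".join(missing))
    lines = [f"# protsar report (v{__version__})", ""]
    desc = pd.read_csv(out / "descriptor_table.csv")
    lines += ["## Dataset", "",
              f"- {len(desc)} compounds",
              f"- class counts: {desc['activity_class'].value_counts().to_dict()}", ""]
    rules_csv = pd.read_csv(out / "decision_rules.csv")
    lines += ["## Decision rules", ""]
    for row in rules_csv.head(5).itertuples(index=False):
        lines.append(
            f"- **{row.label}** -> class {row.target_class}: `{row.clauses}` "
            f"(purity {row.purity:.2f}, coverage {row.coverage:.2f})"
        )
    lines.append("")
    rule_report = pd.read_csv(out / "rule_report.csv")
    space_cols = [c for c in rule_report.columns if c.startswith("space_")]
    lines += ["## Chemical-space coverage", ""]
    for col in space_cols:
        frac = rule_report[col].mean()
        lines.append(f"- {col.removeprefix('space_')}: {100 * frac:.1f}% of compounds")
    lines.append("")
    groups = pd.read_csv(out / "group_profiles.csv")
    trends = groups.drop_duplicates("group")[["group", "trend"]]
    lines += ["## Functional-group trends", ""]
    for trend in ("direct", "inverse"):
        names = trends.loc[trends["trend"] == trend, "group"].tolist()
        lines.append(f"- {trend}: {', '.join(names) if names else 'none'}")
    lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return [path]
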