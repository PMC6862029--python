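"""From-scratch CART classification tree and decision-rule extraction.

The tree is a greedy binary CART minimizing weighted Gini impurity.  At
every node each descriptor is scanned exhaustively; candidate thresholds
are the midpoints between consecutive distinct sorted values (which is why
extracted thresholds on integer descriptors end in .5).  Growth stops on
node purity, maximum depth, or the minimum-leaf-size constraint; no pruning
and no class weighting are applied.  Fitting is fully deterministic: ties
between equally good splits resolve to the lowest feature index (the
canonical panel order) and then the lowest threshold.

Human-readable decision rules are read off the fitted tree: one rule per
leaf whose majority class is the target class, its clauses being the
root-to-leaf comparisons (redundant clauses on one descriptor merged).  A
rule's *purity* is the target-class fraction inside its leaf; its
*coverage* is the fraction of all target-class training samples the leaf
captures.  Rules are ranked by coverage, then purity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "TreeNode",
    "DecisionRule",
    "ActivityTree",
    "fit_tree",
    "extract_rules",
    "apply_rules",
]

_EPS = 1e-12


@dataclass
class TreeNode:
    """One node of the fitted tree."""

    counts: np.ndarray  # per-class sample counts, order = classes_
    depth: int
    feature: str | None = None
    feature_idx: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # samples with value <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def majority(self) -> int:
        return int(np.argmax(self.counts))

    def to_dict(self) -> dict:
        d = {"counts": [int(c) for c in self.counts], "depth": self.depth}
        if not self.is_leaf:
            d.update(
                feature=self.feature,
                feature_idx=self.feature_idx,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts=np.asarray(d["counts"], dtype=np.int64), depth=d["depth"])
        if "feature" in d:
            node.feature = d["feature"]
            node.feature_idx = d["feature_idx"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass(frozen=True)
class DecisionRule:
    """An ordered conjunction of descriptor comparisons targeting a class."""

    label: str
    target_class: str
    clauses: tuple[tuple[str, str, float], ...]  # (descriptor, '<='|'>', threshold)
    purity: float
    coverage: float
    n_samples: int

    def matches(self, row) -> bool:
        for name, op, threshold in self.clauses:
            value = float(row[name])
            ok = value <= threshold if op == "<=" else value > threshold
            if not ok:
                return False
        return True

    def __str__(self) -> str:
        cond = " AND ".join(f"{n} {op} {t:g}" for n, op, t in self.clauses) or "TRUE"
        return (
            f"{self.label}: IF {cond} THEN class {self.target_class} "
            f"(purity {self.purity:.3f}, coverage {self.coverage:.3f}, n={self.n_samples})"
        )


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.dot(p, p))


def _best_split_feature(values: np.ndarray, y_codes: np.ndarray, n_classes: int,
                        min_leaf: int):
    """Best (threshold, weighted_gini) for one feature; None if no valid split.

    Scans the midpoints between consecutive distinct sorted values with
    prefix-summed class counts; among equal-impurity thresholds the lowest
    wins.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = y_codes[order]
    n = v.size
    one_hot = np.zeros((n, n_classes), dtype=np.int64)
    one_hot[np.arange(n), y] = 1
    prefix = np.cumsum(one_hot, axis=0)  # prefix[i] = counts of y[:i+1]
    total = prefix[-1]

    # candidate split after position i (left = first i+1 samples) requires a
    # value change between v[i] and v[i+1]
    idx = np.nonzero(np.diff(v) > 0)[0]
    if idx.size == 0:
        return None
    left_n = idx + 1
    right_n = n - left_n
    valid = (left_n >= min_leaf) & (right_n >= min_leaf)
    idx = idx[valid]
    if idx.size == 0:
        return None
    left_counts = prefix[idx]
    right_counts = total[None, :] - left_counts
    ln = left_counts.sum(axis=1)
    rn = right_counts.sum(axis=1)
    gini_l = 1.0 - np.sum((left_counts / ln[:, None]) ** 2, axis=1)
    gini_r = 1.0 - np.sum((right_counts / rn[:, None]) ** 2, axis=1)
    weighted = (ln * gini_l + rn * gini_r) / n
    best = int(np.argmin(weighted))  # argmin keeps the first (lowest threshold)
    threshold = 0.5 * (v[idx[best]] + v[idx[best] + 1])
    return float(threshold), float(weighted[best])


class ActivityTree(BaseEstimator, ClassifierMixin):
    """CART activity-class classifier with exhaustive midpoint splits.

    Parameters
    ----------
    max_depth : int, default 7
        Maximum tree depth (root at depth 0).
    min_samples_leaf : int, default 5
        Minimum samples in every leaf; splits violating it are discarded.

    Attributes
    ----------
    classes_ : ndarray of class labels (sorted)
    tree_ : TreeNode, the fitted root
    feature_names_in_ : list of descriptor names (tie-break order)
    """

    def __init__(self, max_depth: int = 7, min_samples_leaf: int = 5):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y) -> "ActivityTree":
        X, feature_names = self._validate(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        self.feature_names_in_ = feature_names
        self.n_features_in_ = X.shape[1]
        self.tree_ = self._grow(X, y_codes.astype(np.int64), depth=0)
        return self

    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            return X.astype(float).to_numpy(), names
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return X, [f"x{j}" for j in range(X.shape[1])]

    def _grow(self, X, y_codes, depth) -> TreeNode:
        n_classes = len(self.classes_)
        counts = np.bincount(y_codes, minlength=n_classes).astype(np.int64)
        node = TreeNode(counts=counts, depth=depth)
        n = y_codes.size
        if (
            depth >= self.max_depth
            or n < 2 * self.min_samples_leaf
            or _gini(counts) == 0.0
        ):
            return node
        parent_gini = _gini(counts)
        best = None  # (weighted_gini, feature_idx, threshold)
        for j in range(X.shape[1]):
            res = _best_split_feature(
                X[:, j], y_codes, n_classes, self.min_samples_leaf
            )
            if res is None:
                continue
            threshold, weighted = res
            if best is None or weighted < best[0] - _EPS:
                best = (weighted, j, threshold)
        if best is None or best[0] >= parent_gini - _EPS:
            return node  # no impurity decrease: stop
        _, j, threshold = best
        mask = X[:, j] <= threshold
        node.feature_idx = j
        node.feature = self.feature_names_in_[j]
        node.threshold = threshold
        node.left = self._grow(X[mask], y_codes[mask], depth + 1)
        node.right = self._grow(X[~mask], y_codes[~mask], depth + 1)
        return node

    # -- prediction --------------------------------------------------------
    def _leaf_for(self, row: np.ndarray) -> TreeNode:
        node = self.tree_
        while not node.is_leaf:
            node = node.left if row[node.feature_idx] <= node.threshold else node.right
        return node

    def predict(self, X):
        X, _ = self._validate(X)
        return np.asarray(
            [self.classes_[self._leaf_for(row).majority] for row in X]
        )

    def predict_proba(self, X):
        X, _ = self._validate(X)
        out = np.empty((X.shape[0], len(self.classes_)), dtype=float)
        for i, row in enumerate(X):
            leaf = self._leaf_for(row)
            out[i] = leaf.counts / leaf.counts.sum()
        return out

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": [str(c) for c in self.classes_],
                "feature_names": self.feature_names_in_,
                "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "tree": self.tree_.to_dict(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ActivityTree":
        d = json.loads(text)
        est = cls(max_depth=d["max_depth"], min_samples_leaf=d["min_samples_leaf"])
        est.classes_ = np.asarray(d["classes"])
        est.feature_names_in_ = list(d["feature_names"])
        est.n_features_in_ = len(est.feature_names_in_)
        est.tree_ = TreeNode.from_dict(d["tree"])
        return est


def fit_tree(X, y, max_depth: int = 7, min_samples_leaf: int = 5) -> ActivityTree:
    """Thin wrapper: fit an :class:`ActivityTree` and return it."""
    return ActivityTree(max_depth=max_depth, min_samples_leaf=min_samples_leaf).fit(X, y)


def _merge_clauses(path: list[tuple[str, str, float]]) -> tuple[tuple[str, str, float], ...]:
    """Merge redundant clauses per (descriptor, comparator), keeping order."""
    tightest: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for name, op, threshold in path:
        key = (name, op)
        if key not in tightest:
            tightest[key] = threshold
            order.append(key)
        elif op == "<=":
            tightest[key] = min(tightest[key], threshold)
        else:
            tightest[key] = max(tightest[key], threshold)
    return tuple((name, op, tightest[(name, op)]) for name, op in order)


def extract_rules(estimator: ActivityTree, target_class: str) -> list[DecisionRule]:
    """Decision rules for every leaf whose majority class is ``target_class``.

    Ranked by coverage (descending), then purity; labels ``rule1``,
    ``rule2``, ... follow the ranking.  Returns an empty list (with a
    warning) when no leaf predicts the target class.
    """
    import logging

    logger = logging.getLogger(__name__)
    classes = [str(c) for c in estimator.classes_]
    if str(target_class) not in classes:
        logger.warning("target class %r not among fitted classes", target_class)
        return []
    target_idx = classes.index(str(target_class))
    total_target = 0
    leaves: list[tuple[list, TreeNode]] = []

    def walk(node: TreeNode, path: list):
        nonlocal total_target
        if node.is_leaf:
            total_target += int(node.counts[target_idx])
            if node.majority == target_idx:
                leaves.append((list(path), node))
            return
        walk(node.left, path + [(node.feature, "<=", node.threshold)])
        walk(node.right, path + [(node.feature, ">", node.threshold)])

    walk(estimator.tree_, [])
    if not leaves:
        logger.warning("no leaf with majority class %r", target_class)
        return []
    rules = []
    for path, leaf in leaves:
        n = leaf.n_samples
        n_target = int(leaf.counts[target_idx])
        rules.append(
            (
                _merge_clauses(path),
                n_target / n,
                (n_target / total_target) if total_target else 0.0,
                n,
            )
        )
    rules.sort(key=lambda r: (-r[2], -r[1]))
    return [
        DecisionRule(
            label=f"rule{i + 1}",
            target_class=str(target_class),
            clauses=clauses,
            purity=purity,
            coverage=coverage,
            n_samples=n,
        )
        for i, (clauses, purity, coverage, n) in enumerate(rules)
    ]


def apply_rules(rules: Sequence[DecisionRule], X) -> list[str]:
    """First matching rule's label per sample ('none' when no rule fires)."""
    if isinstance(X, pd.DataFrame):
        rows = (row for _, row in X.iterrows())
    else:
        raise TypeError("apply_rules expects a descriptor DataFrame")
    out = []
    for row in rows:
        fired = "none"
        for rule in rules:
            if rule.matches(row):
                fired = rule.label
                break
        out.append(fired)
    return out


def rules_to_frame(rules: Sequence[DecisionRule]) -> pd.DataFrame:
    """Rules as a tidy exportable table."""
    return pd.DataFrame(
        {
            "label": [r.label for r in rules],
            "target_class": [r.target_class for r in rules],
            "clauses": [
                " AND ".join(f"{n} {op} {t:g}" for n, op, t in r.clauses) for r in rules
            ],
            "purity": [r.purity for r in rules],
            "coverage": [r.coverage for r in rules],
            "n_samples": [r.n_samples for r in rules],
        }
    )
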