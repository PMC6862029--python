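"""CART tree: split correctness against brute force, rules, determinism."""

import numpy as np
import pandas as pd
import pytest

from protsar.descriptors import PANEL_FIELDS
from protsar.tree import ActivityTree, apply_rules, extract_rules, fit_tree, rules_to_frame

from oracles import best_root_split


def frame(X, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


class TestFitTree:
    def test_pure_labels_give_single_pure_leaf(self):
        est = fit_tree(frame([[1.0], [2.0], [3.0]]), ["A", "A", "A"],
                       min_samples_leaf=1)
        assert est.tree_.is_leaf
        assert est.tree_.counts.tolist() == [3]

    def test_one_dimensional_toy_splits_at_midpoint(self):
        X = frame([[1.0], [2.0], [3.0], [4.0]])
        y = ["A", "A", "B", "B"]
        est = fit_tree(X, y, min_samples_leaf=1)
        assert est.tree_.threshold == pytest.approx(2.5)
        assert est.tree_.left.is_leaf and est.tree_.right.is_leaf
        assert est.tree_.left.counts.tolist() == [2, 0]
        assert est.tree_.right.counts.tolist() == [0, 2]

    def test_better_second_feature_chosen(self):
        # feature 0 separates poorly, feature 1 perfectly
        X = frame([[1, 10], [2, 20], [1, 11], [2, 21], [1, 20], [2, 10]])
        y = ["A", "B", "A", "B", "B", "A"]
        est = fit_tree(X, y, min_samples_leaf=1)
        oracle = best_root_split(X.values.tolist(), y, min_leaf=1)
        assert est.tree_.feature_idx == oracle[1]
        assert est.tree_.threshold == pytest.approx(oracle[2])

    def test_constant_features_yield_single_leaf(self):
        est = fit_tree(frame([[1.0], [1.0], [1.0], [1.0]]), ["A", "B", "A", "B"],
                       min_samples_leaf=1)
        assert est.tree_.is_leaf

    def test_too_few_samples_yield_single_leaf(self):
        est = fit_tree(frame([[1.0], [9.0]]), ["A", "B"], min_samples_leaf=5)
        assert est.tree_.is_leaf

    def test_min_samples_leaf_respected_everywhere(self, synthetic_dataset):
        records, panel = synthetic_dataset
        est = fit_tree(panel[list(PANEL_FIELDS)],
                       [r.activity_class for r in records])
        leaves = []

        def walk(node):
            if node.is_leaf:
                leaves.append(node)
            else:
                walk(node.left), walk(node.right)

        walk(est.tree_)
        assert all(leaf.n_samples >= 5 for leaf in leaves)
        assert all(leaf.depth <= 7 for leaf in leaves)

    def test_children_partition_parent_counts(self, synthetic_dataset):
        records, panel = synthetic_dataset
        est = fit_tree(panel[list(PANEL_FIELDS)],
                       [r.activity_class for r in records])

        def walk(node):
            if node.is_leaf:
                return
            assert (node.left.counts + node.right.counts == node.counts).all()
            walk(node.left), walk(node.right)

        walk(est.tree_)

    def test_root_split_matches_bruteforce_on_random_data(self, rng):
        """Exhaustive-oracle equivalence on small random datasets."""
        for trial in range(25):
            n = int(rng.integers(8, 61))
            d = int(rng.integers(1, 4))
            if trial % 2:
                X = rng.integers(0, 6, size=(n, d)).astype(float)
            else:
                X = np.round(rng.normal(size=(n, d)), 2)
            y = rng.choice(["A", "B", "C"], size=n).tolist()
            est = fit_tree(frame(X), y, min_samples_leaf=1, max_depth=1)
            oracle = best_root_split(X.tolist(), y, min_leaf=1)
            if oracle is None:
                assert est.tree_.is_leaf
                continue
            from oracles import gini
            if oracle[0] >= gini([y.count(c) for c in set(y)]) - 1e-12:
                assert est.tree_.is_leaf  # no impurity decrease available
                continue
            assert est.tree_.feature_idx == oracle[1], trial
            assert est.tree_.threshold == pytest.approx(oracle[2]), trial

    def test_determinism_structurally_identical(self, synthetic_dataset):
        records, panel = synthetic_dataset
        X = panel[list(PANEL_FIELDS)]
        y = [r.activity_class for r in records]
        assert fit_tree(X, y).to_json() == fit_tree(X, y).to_json()

    def test_sklearn_estimator_contract(self):
        est = ActivityTree(max_depth=3, min_samples_leaf=2)
        assert est.get_params() == {"max_depth": 3, "min_samples_leaf": 2}
        est.set_params(max_depth=4)
        X = frame([[1.0], [2.0], [3.0], [4.0]])
        est.fit(X, ["A", "A", "B", "B"])
        assert list(est.classes_) == ["A", "B"]
        assert est.predict(X).tolist() == ["A", "A", "B", "B"]
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_tree(frame([[1.0], [np.nan]]), ["A", "B"], min_samples_leaf=1)

    def test_json_round_trip_preserves_predictions(self, synthetic_dataset):
        records, panel = synthetic_dataset
        X = panel[list(PANEL_FIELDS)]
        est = fit_tree(X, [r.activity_class for r in records])
        clone = ActivityTree.from_json(est.to_json())
        assert (clone.predict(X) == est.predict(X)).all()


class TestRuleExtraction:
    def test_pure_single_leaf_gives_trivial_rule(self):
        est = fit_tree(frame([[1.0], [2.0]]), ["A", "A"], min_samples_leaf=1)
        rules = extract_rules(est, "A")
        assert len(rules) == 1
        assert rules[0].clauses == ()
        assert rules[0].purity == 1.0 and rules[0].coverage == 1.0

    def test_one_dimensional_toy_rule(self):
        est = fit_tree(frame([[1.0], [2.0], [3.0], [4.0]]), ["A", "A", "B", "B"],
                       min_samples_leaf=1)
        rules = extract_rules(est, "A")
        assert rules[0].clauses == (("x0", "<=", 2.5),)
        assert rules[0].purity == 1.0 and rules[0].coverage == 1.0

    def test_absent_target_returns_empty(self):
        est = fit_tree(frame([[1.0], [2.0]]), ["B", "B"], min_samples_leaf=1)
        assert extract_rules(est, "A") == []

    def test_redundant_clauses_merged(self):
        # nested splits on the same feature produce one merged clause each way
        rng = np.random.default_rng(3)
        X = frame(rng.uniform(0, 10, size=(200, 1)))
        y = ["A" if 2 < v <= 5 else "B" for v in X["x0"]]
        est = fit_tree(X, y, min_samples_leaf=1)
        for rule in extract_rules(est, "A"):
            keys = [(n, op) for n, op, _ in rule.clauses]
            assert len(keys) == len(set(keys))

    def test_coverage_bookkeeping_two_ways(self, synthetic_dataset):
        """Leaf-count coverage equals an apply_rules recount, exactly."""
        records, panel = synthetic_dataset
        X = panel[list(PANEL_FIELDS)]
        y = [r.activity_class for r in records]
        est = fit_tree(X, y)
        rules = extract_rules(est, "A")
        total_a = y.count("A")
        # leaves with majority A capture sum(coverage)*total_a compounds
        assert sum(r.purity * r.n_samples for r in rules) == pytest.approx(
            sum(r.coverage for r in rules) * total_a
        )
        for rule in rules:
            fired = [rule.matches(X.iloc[i]) for i in range(len(X))]
            captured = sum(1 for f, cls in zip(fired, y) if f and cls == "A")
            # the rule region is exactly its leaf: recount matches leaf count
            assert captured == round(rule.coverage * total_a)

    def test_rules_consistent_with_tree_prediction(self, synthetic_dataset):
        records, panel = synthetic_dataset
        X = panel[list(PANEL_FIELDS)]
        y = [r.activity_class for r in records]
        est = fit_tree(X, y)
        rules = extract_rules(est, "A")
        fired = apply_rules(rules, X)
        pred = est.predict(X)
        for label, p in zip(fired, pred):
            assert (label != "none") == (p == "A")

    def test_ranking_by_coverage_then_purity(self, synthetic_full):
        records, panel = synthetic_full
        est = fit_tree(panel[list(PANEL_FIELDS)], [r.activity_class for r in records])
        rules = extract_rules(est, "A")
        keys = [(-r.coverage, -r.purity) for r in rules]
        assert keys == sorted(keys)
        assert [r.label for r in rules] == [f"rule{i+1}" for i in range(len(rules))]

    def test_rules_frame_export(self, synthetic_dataset):
        records, panel = synthetic_dataset
        est = fit_tree(panel[list(PANEL_FIELDS)], [r.activity_class for r in records])
        out = rules_to_frame(extract_rules(est, "A"))
        assert {"label", "clauses", "purity", "coverage"} <= set(out.columns)


class TestSklearnCrossCheck:
    def test_matches_reference_cart_on_synthetic_data(self, synthetic_dataset):
        """Independent library CART agrees on the root split and accuracy."""
        from sklearn.tree import DecisionTreeClassifier

        records, panel = synthetic_dataset
        X = panel[list(PANEL_FIELDS)].astype(float)
        y = [r.activity_class for r in records]
        ours = fit_tree(X, y)
        ref = DecisionTreeClassifier(
            max_depth=7, min_samples_leaf=5, random_state=0
        ).fit(X, y)
        assert X.columns[ref.tree_.feature[0]] == ours.tree_.feature
        assert ref.tree_.threshold[0] == pytest.approx(ours.tree_.threshold, rel=1e-6)
        ours_acc = (ours.predict(X) == np.asarray(y)).mean()
        ref_acc = (ref.predict(X) == np.asarray(y)).mean()
        assert abs(ours_acc - ref_acc) <= 0.02
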