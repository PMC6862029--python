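"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation code paths (and scipy/sklearn):
plain-Python enumeration only.
"""

from math import comb, inf


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by full enumeration over fixed margins.

    Sums hypergeometric probabilities of every table whose probability does
    not exceed the observed table's (within a tiny relative tolerance).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    denom = comb(n, c1)

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def bh_stepup(pvals):
    """Benjamini-Hochberg step-up by direct application of the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = inf
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top  # 1-based rank of this p-value
        running_min = min(running_min, pvals[idx] * m / rank)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def gini(counts) -> float:
    n = sum(counts)
    if n == 0:
        return 0.0
    return 1.0 - sum((c / n) ** 2 for c in counts)


def best_root_split(X, y, min_leaf=1):
    """Exhaustive CART root-split search in plain Python.

    Returns (weighted_gini, feature, threshold) minimizing weighted Gini
    impurity over every feature and every midpoint between consecutive
    distinct sorted values; ties resolve to the lowest feature index, then
    the lowest threshold. None when no valid split exists.
    """
    n = len(y)
    classes = sorted(set(y))
    best = None
    for j in range(len(X[0])):
        values = sorted(set(row[j] for row in X))
        for lo, hi in zip(values, values[1:]):
            threshold = (lo + hi) / 2.0
            left = [y[i] for i in range(n) if X[i][j] <= threshold]
            right = [y[i] for i in range(n) if X[i][j] > threshold]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            lc = [left.count(c) for c in classes]
            rc = [right.count(c) for c in classes]
            w = (len(left) * gini(lc) + len(right) * gini(rc)) / n
            if best is None or w < best[0] - 1e-12:
                best = (w, j, threshold)
    return best
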