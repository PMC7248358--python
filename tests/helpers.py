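"""Shared test utilities: exact-rational oracles independent of the package.

The split-search oracle enumerates every (feature, midpoint-threshold) pair
with `fractions.Fraction` arithmetic, so its Gini decreases are exact and its
chosen split cannot be contaminated by the package's floating-point path.
"""

from fractions import Fraction

import numpy as np


def exact_gini(labels) -> Fraction:
    n = len(labels)
    if n == 0:
        return Fraction(0)
    counts = {}
    for v in labels:
        counts[v] = counts.get(v, 0) + 1
    return 1 - sum(Fraction(c, n) ** 2 for c in counts.values())


def oracle_best_split(X, y):
    """Exhaustively enumerate axis-aligned splits; return the best.

    Returns ``(feature, threshold, decrease)`` with Fraction threshold and
    decrease under the weighted (child-size) convention, or None when the node
    is pure or no valid threshold exists (zero-decrease splits of impure nodes
    are acceptable, mirroring the package's CART rule). Ties break to the
    lowest feature index, then the lowest threshold.
    """
    X = [[Fraction(v).limit_denominator(10**6) for v in row] for row in np.asarray(X, dtype=float)]
    y = list(y)
    n = len(y)
    parent = exact_gini(y)
    if parent == 0:
        return None
    best = None
    n_features = len(X[0])
    for f in range(n_features):
        vals = sorted(set(row[f] for row in X))
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2
            left = [y[i] for i in range(n) if X[i][f] <= thr]
            right = [y[i] for i in range(n) if X[i][f] > thr]
            dec = (
                parent
                - Fraction(len(left), n) * exact_gini(left)
                - Fraction(len(right), n) * exact_gini(right)
            )
            key = (-dec, f, thr)
            if best is None or key < best[0]:
                best = (key, (f, thr, dec))
    return None if best is None else best[1]


def random_small_dataset(rng):
    """One dataset from the small-problem space: 2-8 samples, 1-3 binary
    features, 2-3 classes (every class present at least once)."""
    n = int(rng.integers(2, 9))
    f = int(rng.integers(1, 4))
    k = int(rng.integers(2, 4))
    X = rng.integers(0, 2, size=(n, f)).astype(float)
    while True:
        y = rng.integers(0, k, size=n)
        if len(np.unique(y)) >= 2:
            break
    return X, y
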