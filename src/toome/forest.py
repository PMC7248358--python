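"""Bagged decision-tree ensemble with explicit Gini-importance bookkeeping.

This is a native CART-style random forest written so that the quantity driving
tissue-of-origin gene selection — the cumulative Gini-impurity decrease of each
feature — is a first-class, inspectable output rather than a by-product.

Per split node the impurity change can be accounted for under two conventions:

``weighted`` (default)
    ``G(parent) - (n_l/n) G(left) - (n_r/n) G(right)`` — the standard CART
    impurity decrease, guaranteed non-negative for any accepted split.
``literal``
    ``G(parent) - G(left) - G(right)`` — the unweighted difference, which can
    be negative and yields far more conservative trees when used as the split
    criterion.

A tree's importance for feature *i* sums the contributions of all nodes split
on *i*; a forest's importance is the sum over its trees. Under ``weighted``
each node's decrease is additionally scaled by the fraction of the tree's
training samples reaching that node (the standard mean-decrease-impurity
accumulation — without it, deep splits on continuous noise features would
swamp genuine sparse-feature signal). Under ``literal`` the decreases are
summed as-is.

Trees serialize to plain JSON (no pickle) so fitted models are diffable and
portable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ContractError, ParameterError, ShapeError, StructureError

Convention = Literal["weighted", "literal"]


def gini(p: np.ndarray) -> float:
    """Gini impurity ``1 - sum(p_k^2)`` of a class-weight simplex vector.

    Parameters
    ----------
    p
        Non-negative class weights summing to 1 (tolerance 1e-9).

    Returns
    -------
    float
        Impurity in ``[0, 1 - 1/K]`` for ``K = len(p)`` classes.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12):
        raise ContractError("class weights must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ContractError(f"class weights must sum to 1, got {total!r}")
    return float(1.0 - np.dot(p, p))


def _gini_from_counts(counts: np.ndarray, n: int) -> float:
    if n == 0:
        return 0.0
    frac = counts / n
    return float(1.0 - np.dot(frac, frac))


@dataclass
class TreeNode:
    """One node of a fitted decision tree.

    Internal nodes carry the split (``feature_index``, ``threshold``) and both
    children; leaves carry neither. Every node keeps its class counts and Gini
    impurity so feature importances can be re-derived by walking the tree.
    """

    n_samples: int
    class_counts: np.ndarray
    gini: float
    feature_index: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def leaf_class(self) -> int:
        """Majority class index; ties go to the lowest index (and therefore,
        with lexicographically sorted labels, to the smallest label)."""
        return int(np.argmax(self.class_counts))

    def to_dict(self) -> dict:
        d = {
            "n_samples": int(self.n_samples),
            "class_counts": [int(c) for c in self.class_counts],
            "gini": self.gini,
        }
        if not self.is_leaf:
            d["feature_index"] = int(self.feature_index)
            d["threshold"] = float(self.threshold)
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            n_samples=d["n_samples"],
            class_counts=np.asarray(d["class_counts"], dtype=float),
            gini=d["gini"],
        )
        if "feature_index" in d:
            node.feature_index = d["feature_index"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def node_importance(
    parent: TreeNode,
    left: TreeNode,
    right: TreeNode,
    convention: Convention = "weighted",
) -> float:
    """Gini-impurity change of one split under the chosen accounting convention."""
    if left.n_samples + right.n_samples != parent.n_samples:
        raise StructureError(
            f"child sizes {left.n_samples}+{right.n_samples} != parent {parent.n_samples}"
        )
    if convention == "literal":
        return parent.gini - left.gini - right.gini
    if convention == "weighted":
        n = parent.n_samples
        return (
            parent.gini
            - (left.n_samples / n) * left.gini
            - (right.n_samples / n) * right.gini
        )
    raise ParameterError(f"unknown convention {convention!r}")


@dataclass
class DecisionTree:
    """A fitted tree plus its per-feature importance accumulator."""

    root: TreeNode
    node_importances: dict[int, float] = field(default_factory=dict)
    bootstrap_indices: np.ndarray | None = None

    def predict_index(self, X: np.ndarray) -> np.ndarray:
        """Leaf-class index for each row of X."""
        out = np.empty(X.shape[0], dtype=np.intp)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature_index] <= node.threshold else node.right
            out[i] = node.leaf_class
        return out

    def rederive_importances(self, convention: Convention = "weighted") -> dict[int, float]:
        """Re-walk the stored tree and re-sum per-node contributions per feature.

        Independent of the accumulator filled during fitting; used to verify
        that the tree-level importance really is the sum over its split nodes.
        Under ``weighted`` each node's decrease carries the standard
        node-probability factor ``n_node / n_root``; under ``literal`` the raw
        decreases are summed.
        """
        acc: dict[int, float] = {}
        n_root = self.root.n_samples
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            dec = node_importance(node, node.left, node.right, convention)
            if convention == "weighted":
                dec *= node.n_samples / n_root
            acc[node.feature_index] = acc.get(node.feature_index, 0.0) + dec
            stack.append(node.right)
            stack.append(node.left)
        return acc

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "node_importances": {str(k): v for k, v in self.node_importances.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            node_importances={int(k): v for k, v in d["node_importances"].items()},
        )


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    candidates: np.ndarray,
    n_classes: int,
    parent_gini: float,
    convention: Convention,
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, decrease) over the candidate features.

    Vectorized over candidates: one argsort per feature block, prefix-sum class
    counts, impurity evaluated at every midpoint between consecutive distinct
    values. Ties are broken by lowest feature index, then lowest threshold.
    Zero-decrease splits of impure nodes are accepted (the XOR pattern needs
    one); under the weighted convention the decrease is never negative, while
    under ``literal`` a node whose best split has negative decrease becomes a
    leaf. Returns None when no acceptable split exists.
    """
    n = idx.size
    Xn = X[np.ix_(idx, candidates)]
    yn = y[idx]
    order = np.argsort(Xn, axis=0, kind="stable")
    xs = np.take_along_axis(Xn, order, axis=0)  # n x f, per-column sorted
    ys = yn[order]  # n x f

    onehot = np.zeros((n, candidates.size, n_classes))
    np.put_along_axis(onehot, ys[:, :, None], 1.0, axis=2)
    left_counts = np.cumsum(onehot, axis=0)  # cut after position i -> rows :i+1 left
    total = left_counts[-1]  # f x K

    nl = np.arange(1, n + 1, dtype=float)[:, None]
    nr = n - nl
    with np.errstate(divide="ignore", invalid="ignore"):
        gl = 1.0 - np.sum((left_counts / nl[:, :, None]) ** 2, axis=2)
        gr_counts = total[None] - left_counts
        gr = np.where(
            nr > 0, 1.0 - np.sum((gr_counts / np.maximum(nr, 1)[:, :, None]) ** 2, axis=2), 0.0
        )
    if convention == "literal":
        decrease = parent_gini - gl - gr
    else:
        decrease = parent_gini - (nl / n) * gl - (nr / n) * gr

    valid = np.zeros_like(decrease, dtype=bool)
    valid[:-1] = xs[1:] > xs[:-1]  # only between distinct consecutive values
    decrease = np.where(valid, decrease, -np.inf)

    # candidates are sorted ascending and near-ties (float round-off of exact
    # rational ties) resolve to the first hit, i.e. the lowest feature index
    # and then the lowest threshold
    col_best = decrease.max(axis=0)
    m = col_best.max()
    if not np.isfinite(m) or m < -1e-12:
        return None
    j = int(np.argmax(col_best >= m - 1e-12))
    i = int(np.argmax(decrease[:, j] >= col_best[j] - 1e-12))
    thr = 0.5 * (xs[i, j] + xs[i + 1, j])
    return int(candidates[j]), float(thr), max(float(decrease[i, j]), 0.0)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
    min_samples_split: int = 2,
    convention: Convention = "weighted",
) -> DecisionTree:
    """Grow a decision tree by greedy recursive partitioning.

    At each node ``mtry`` features are sampled without replacement and the
    split maximizing the impurity decrease (under ``convention``) is taken;
    thresholds are midpoints between consecutive distinct sorted values.
    Growth stops at pure nodes, nodes below ``min_samples_split``, nodes with
    no valid threshold, and (under ``literal``) nodes whose best split has
    negative decrease. ``y`` holds class indices in ``range(n_classes)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ShapeError("X must be 2-D with one label per row")
    n_features = X.shape[1]
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(n_features))))
    if not 1 <= mtry <= n_features:
        raise ParameterError(f"mtry={mtry} out of range [1, {n_features}]")
    if rng is None:
        rng = np.random.default_rng()

    importances: dict[int, float] = {}
    n_root = X.shape[0]

    def build(idx: np.ndarray) -> TreeNode:
        counts = np.bincount(y[idx], minlength=n_classes).astype(float)
        node = TreeNode(
            n_samples=int(idx.size),
            class_counts=counts,
            gini=_gini_from_counts(counts, idx.size),
        )
        if idx.size < min_samples_split or node.gini == 0.0:
            return node
        cand = (
            np.arange(n_features)
            if mtry == n_features
            else np.sort(rng.choice(n_features, size=mtry, replace=False))
        )
        split = _best_split(X, y, idx, np.asarray(cand), n_classes, node.gini, convention)
        if split is None:
            return node
        feat, thr, dec = split
        mask = X[idx, feat] <= thr
        node.feature_index = feat
        node.threshold = thr
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        contrib = dec * (idx.size / n_root) if convention == "weighted" else dec
        importances[feat] = importances.get(feat, 0.0) + contrib
        return node

    root = build(np.arange(X.shape[0]))
    return DecisionTree(root=root, node_importances=importances)


@dataclass
class Forest:
    """Bagged ensemble of decision trees sharing one class-label ordering."""

    trees: list[DecisionTree]
    class_labels: list[str]
    n_features: int
    mtry: int
    rng_seed: int | None = None
    convention: Convention = "weighted"

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Vote fractions per class; each row sums to 1."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ShapeError(
                f"expected {self.n_features} feature columns, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        votes = np.zeros((X.shape[0], self.n_classes))
        for tree in self.trees:
            pred = tree.predict_index(X)
            votes[np.arange(X.shape[0]), pred] += 1.0
        return votes / len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote labels; vote ties go to the lexicographically
        smallest class label (labels are stored sorted, argmax takes the
        first maximum)."""
        proba = self.predict_proba(X)
        labels = np.asarray(self.class_labels, dtype=object)
        return labels[np.argmax(proba, axis=1)]

    def feature_importances(self) -> np.ndarray:
        """Summed per-tree Gini importances, length ``n_features``."""
        out = np.zeros(self.n_features)
        for tree in self.trees:
            for feat, imp in tree.node_importances.items():
                out[feat] += imp
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "class_labels": self.class_labels,
            "n_features": self.n_features,
            "mtry": self.mtry,
            "rng_seed": self.rng_seed,
            "convention": self.convention,
            "trees": [t.to_dict() for t in self.trees],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "Forest":
        if "\n" not in source and source.strip() and not source.lstrip().startswith("{"):
            with open(source) as fh:
                source = fh.read()
        d = json.loads(source)
        return cls(
            trees=[DecisionTree.from_dict(t) for t in d["trees"]],
            class_labels=d["class_labels"],
            n_features=d["n_features"],
            mtry=d["mtry"],
            rng_seed=d["rng_seed"],
            convention=d["convention"],
        )


def fit_forest(
    X: np.ndarray,
    y,
    n_trees: int = 500,
    mtry: int | None = None,
    rng_seed: int | None = None,
    min_samples_split: int = 2,
    convention: Convention = "weighted",
    bootstrap: bool = True,
) -> Forest:
    """Fit a bagged forest: each tree is grown on a size-M resample drawn with
    replacement, using an independent substream of the seeded generator.

    ``y`` may be any label array; class labels are ordered lexicographically.
    Deterministic given ``(X, y, n_trees, mtry, rng_seed)``. ``bootstrap=False``
    (every tree sees the full sample) exists for testing degenerate ensembles.
    """
    if n_trees < 1:
        raise ParameterError("n_trees must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_labels = sorted(str(v) for v in np.unique(y))
    label_to_idx = {lab: i for i, lab in enumerate(class_labels)}
    y_idx = np.asarray([label_to_idx[str(v)] for v in y], dtype=np.intp)
    n_features = X.shape[1]
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(n_features))))

    seedseq = np.random.SeedSequence(rng_seed)
    children = seedseq.spawn(n_trees)
    trees = []
    M = X.shape[0]
    for child in children:
        rng = np.random.default_rng(child)
        if bootstrap:
            boot = rng.integers(0, M, size=M)
        else:
            boot = np.arange(M)
        tree = fit_tree(
            X[boot],
            y_idx[boot],
            n_classes=len(class_labels),
            mtry=mtry,
            rng=rng,
            min_samples_split=min_samples_split,
            convention=convention,
        )
        tree.bootstrap_indices = boot
        trees.append(tree)
    return Forest(
        trees=trees,
        class_labels=class_labels,
        n_features=n_features,
        mtry=mtry,
        rng_seed=rng_seed,
        convention=convention,
    )
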