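"""C4.5-style decision-tree induction, prediction and cross-validation.

Trees are grown top-down on numeric features: at every node each feature is
scanned over all midpoints between sorted distinct values, the information
gain (parent entropy minus instance-weighted child entropy, in bits) is
computed for every candidate binary split, and the split with the highest
gain is taken.  Growth stops when a node is pure, too small, or no split
achieves positive gain.  Pruning is pessimistic error-based subtree
replacement with confidence factor 0.25 and a minimum of 2 instances per
leaf — the documented defaults of the common open implementation of the
algorithm.

Ties between equal-gain splits are broken toward the lowest feature index
and then the smallest threshold, and rows sitting exactly on a threshold are
routed to the <= branch, so induction and prediction are fully
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "TreeNode",
    "entropy",
    "information_gain",
    "build_tree",
    "predict",
    "cross_validate",
    "stratified_folds",
    "render_tree",
]

_GAIN_EPS = 1e-12


def entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a class-count vector; 0 log 0 = 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty distribution")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def information_gain(
    column: np.ndarray, labels: np.ndarray, threshold: float, n_classes: int
) -> float:
    """Gain in bits of the binary split ``column <= threshold``.

    A degenerate split (one side empty) carries no information and returns 0.
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    left = column <= threshold
    n_left = int(left.sum())
    if n_left == 0 or n_left == len(column):
        return 0.0
    parent = np.bincount(labels, minlength=n_classes)
    lc = np.bincount(labels[left], minlength=n_classes)
    rc = parent - lc
    n = len(labels)
    gain = (
        entropy(parent)
        - n_left / n * entropy(lc)
        - (n - n_left) / n * entropy(rc)
    )
    return float(max(gain, 0.0))


@dataclass
class TreeNode:
    """One node of a decision tree.

    Internal nodes hold a feature index/name and a threshold (rows with
    value <= threshold go left); leaves hold the majority class.  Every node
    keeps the class counts of the training instances that reached it, so
    leaves can report "n reaching / n wrong" and class probabilities.
    """

    counts: np.ndarray
    feature: int | None = None
    feature_name: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(np.sum(self.counts))

    @property
    def klass(self) -> int:
        return int(np.argmax(self.counts))  # first index wins ties

    @property
    def n_wrong(self) -> int:
        return self.n - int(self.counts[self.klass])

    def to_dict(self) -> dict:
        d: dict = {"counts": [int(c) for c in self.counts]}
        if not self.is_leaf:
            d.update(
                feature=int(self.feature),
                feature_name=self.feature_name,
                threshold=float(self.threshold),
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts=np.asarray(d["counts"], dtype=int))
        if "feature" in d:
            node.feature = int(d["feature"])
            node.feature_name = d.get("feature_name")
            node.threshold = float(d["threshold"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _best_split_for_feature(
    values: np.ndarray, labels: np.ndarray, n_classes: int, min_leaf: int
) -> tuple[float, float] | None:
    """Best (gain, threshold) over all midpoints of one feature, or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; both children must keep at least ``min_leaf`` instances.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    n = len(v)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    cum = np.cumsum(onehot, axis=0)  # cum[i] = class counts of first i+1 rows

    # split after position i (left = rows 0..i) is valid where value changes
    change = np.nonzero(np.diff(v) > 0)[0]
    if len(change) == 0:
        return None
    sizes_left = change + 1
    valid = (sizes_left >= min_leaf) & (n - sizes_left >= min_leaf)
    change = change[valid]
    if len(change) == 0:
        return None
    lc = cum[change]
    total = cum[-1]
    rc = total - lc
    nl = lc.sum(axis=1)
    nr = rc.sum(axis=1)

    def _h(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / totals[:, None]
            term = np.where(p > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=1)

    parent_h = entropy(total)
    gains = parent_h - (nl * _h(lc, nl) + nr * _h(rc, nr)) / n
    best = int(np.argmax(gains))  # first occurrence: smallest threshold
    gain = float(gains[best])
    threshold = 0.5 * (v[change[best]] + v[change[best] + 1])
    return gain, float(threshold)


def build_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    feature_names: Sequence[str] | None = None,
    min_leaf: int = 2,
    confidence: float = 0.25,
    prune: bool = True,
) -> TreeNode:
    """Grow (and optionally prune) a C4.5 tree on numeric features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("cannot build a tree from zero instances")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]

    def grow(idx: np.ndarray) -> TreeNode:
        yy = y[idx]
        counts = np.bincount(yy, minlength=n_classes)
        node = TreeNode(counts=counts)
        if np.count_nonzero(counts) <= 1 or len(idx) < 2 * min_leaf:
            return node
        best: tuple[float, int, float] | None = None
        for f in range(X.shape[1]):
            res = _best_split_for_feature(X[idx, f], yy, n_classes, min_leaf)
            if res is None:
                continue
            gain, thr = res
            if best is None or gain > best[0] + _GAIN_EPS:
                best = (gain, f, thr)
        if best is None or best[0] <= _GAIN_EPS:
            return node
        _, f, thr = best
        node.feature = f
        node.feature_name = feature_names[f]
        node.threshold = thr
        mask = X[idx, f] <= thr
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    root = grow(np.arange(len(X)))
    if prune:
        _prune(root, confidence)
    return root


def _pessimistic_errors(node_n: int, node_wrong: int, z: float) -> float:
    """Upper confidence bound on the error count of a leaf (Wilson interval
    on the training error rate, the classic pessimistic-pruning estimate)."""
    if node_n == 0:
        return 0.0
    f = node_wrong / node_n
    n = node_n
    bound = (
        f + z * z / (2 * n) + z * np.sqrt(f * (1 - f) / n + z * z / (4 * n * n))
    ) / (1 + z * z / n)
    return float(bound * n)


def _prune(node: TreeNode, confidence: float) -> float:
    """Post-order subtree replacement; returns the node's estimated errors."""
    z = float(norm.ppf(1.0 - confidence))
    return _prune_rec(node, z)


def _prune_rec(node: TreeNode, z: float) -> float:
    if node.is_leaf:
        return _pessimistic_errors(node.n, node.n_wrong, z)
    subtree_err = _prune_rec(node.left, z) + _prune_rec(node.right, z)
    leaf_err = _pessimistic_errors(node.n, node.n_wrong, z)
    if leaf_err <= subtree_err + 0.1:
        node.feature = None
        node.feature_name = None
        node.threshold = None
        node.left = node.right = None
        return leaf_err
    return subtree_err


def predict(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Route rows from root to leaf; values equal to a threshold go left."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite feature values")
    out = np.empty(len(X), dtype=int)
    for i, row in enumerate(X):
        node = tree
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out[i] = node.klass
    return out


def predict_proba(tree: TreeNode, row: np.ndarray) -> np.ndarray:
    """Class frequencies of the leaf that ``row`` reaches."""
    node = tree
    row = np.asarray(row, dtype=float)
    while not node.is_leaf:
        node = node.left if row[node.feature] <= node.threshold else node.right
    total = max(node.n, 1)
    return node.counts / total


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal each class's shuffled instances round-robin over k folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    counts = np.bincount(y)
    if counts[counts > 0].min() < 1:
        raise ValueError("every class needs at least one instance")
    start = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(int(i))
        start += len(idx)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    k: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    stratified: bool = True,
    **tree_params,
) -> tuple[float, np.ndarray]:
    """k-fold cross-validation; returns pooled accuracy and the confusion
    matrix (rows = true class, columns = predicted class)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k > len(y):
        raise ValueError(f"k={k} exceeds {len(y)} instances")
    rng = np.random.default_rng(seed)
    if stratified and np.bincount(y, minlength=n_classes).min() < k:
        warnings.warn(
            "a class has fewer instances than folds; "
            "falling back to unstratified folds",
            stacklevel=2,
        )
        stratified = False
    if stratified:
        folds = stratified_folds(y, k, rng)
    else:
        perm = rng.permutation(len(y))
        folds = [np.sort(f) for f in np.array_split(perm, k)]
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for fold in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        tree = build_tree(
            X[mask], y[mask], n_classes, feature_names=feature_names, **tree_params
        )
        pred = predict(tree, X[fold])
        for t, p in zip(y[fold], pred):
            confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    return accuracy, confusion


def render_tree(
    tree: TreeNode, class_names: Sequence[str], indent: str = ""
) -> str:
    """Indented text rendering with "class (n reaching/n wrong)" leaves."""
    if tree.is_leaf:
        return f"{indent}{class_names[tree.klass]} ({tree.n}/{tree.n_wrong})"
    lines = [
        f"{indent}{tree.feature_name} <= {tree.threshold:g}",
        render_tree(tree.left, class_names, indent + "|   "),
        f"{indent}{tree.feature_name} > {tree.threshold:g}",
        render_tree(tree.right, class_names, indent + "|   "),
    ]
    return "\n".join(lines)
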