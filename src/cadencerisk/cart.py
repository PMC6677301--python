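"""From-scratch CART classifier on cadence-band minutes.

Binary recursive partitioning with Gini impurity: every split is the
exhaustive best over all features and all midpoints between consecutive
distinct observed values, accepted only if the relative impurity decrease
reaches the complexity parameter ``cp`` and both children satisfy the
minimum leaf size.  Pre-pruning via the cp threshold (no cost-complexity
pruning pass).  Ties between equally good splits are broken by lower
feature index, then lower cutpoint, making the tree deterministic and
independent of row order.

Evaluation mirrors the repeated-holdout protocol: 1000 random
label-stratified 80/20 train/test splits, reporting the mean test
accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CARTConfig",
    "TreeNode",
    "SplitRule",
    "HoldoutResult",
    "gini",
    "best_split",
    "grow_tree",
    "predict",
    "predict_one",
    "repeated_holdout",
    "render_tree",
    "tree_to_json",
    "tree_from_json",
    "CadenceBandTree",
]


@dataclass
class CARTConfig:
    min_split: int = 20     # don't attempt to split smaller nodes
    min_leaf: int = 7       # minimum child size
    cp: float = 0.01        # minimum relative impurity decrease
    max_depth: int = 30

    def __post_init__(self):
        if self.min_leaf > self.min_split:
            raise ValueError("min_leaf must be <= min_split")
        if self.cp < 0:
            raise ValueError("cp must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class SplitRule:
    feature: int
    cutpoint: float          # left child: feature < cutpoint
    gain: float              # absolute impurity decrease
    rel_gain: float          # gain / parent impurity


@dataclass
class TreeNode:
    counts: tuple            # (n_class0, n_class1) — 0 = no risk, 1 = at risk
    fraction: float          # of the training sample
    prediction: int
    split: Optional[SplitRule] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class HoldoutResult:
    n_reps: int
    train_fraction: float
    accuracies: np.ndarray
    seed: object
    mean_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)

    def __post_init__(self):
        self.mean_accuracy = float(np.mean(self.accuracies))
        self.sd_accuracy = float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def gini(counts) -> float:
    """Two-class Gini impurity 1 - sum p_k^2, in [0, 0.5]."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or c.sum() == 0:
        raise ValueError("class counts must be non-negative and not all zero")
    p = c / c.sum()
    return float(1.0 - np.sum(p * p))


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def best_split(X: np.ndarray, y: np.ndarray,
               config: CARTConfig | None = None,
               n_root: Optional[int] = None,
               imp_root: Optional[float] = None) -> Optional[SplitRule]:
    """Exhaustive best (feature, cutpoint) by weighted Gini decrease.

    Candidates are midpoints between consecutive distinct values of each
    feature.  A split is accepted only if it reduces the *tree-total*
    impurity by at least ``cp`` relative to the root node's contribution:
    (n_node / n_root) * gain >= cp * imp_root (the recursive-partitioning
    convention, so deep low-n splits cannot live off noise).  When called
    on a root node, n_root/imp_root default to the node itself.  Returns
    None if the node is too small, pure, below the cp gate, or if every
    candidate violates min_leaf.
    """
    config = config or CARTConfig()
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    if n < config.min_split:
        return None
    n1 = int(y.sum())
    parent_counts = (n - n1, n1)
    imp_parent = gini(parent_counts)
    if imp_parent == 0.0:
        return None
    if n_root is None:
        n_root = n
    if imp_root is None:
        imp_root = imp_parent

    best: Optional[SplitRule] = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        # positions where the value changes: candidate boundaries
        change = np.nonzero(xs[1:] > xs[:-1])[0]  # split after index i
        if len(change) == 0:
            continue
        cum1 = np.cumsum(ys)
        nl = change + 1
        nr = n - nl
        ok = (nl >= config.min_leaf) & (nr >= config.min_leaf)
        if not ok.any():
            continue
        nl, nr, ch = nl[ok], nr[ok], change[ok]
        l1 = cum1[ch].astype(float)
        l0 = nl - l1
        r1 = n1 - l1
        r0 = nr - r1
        imp_l = 1.0 - (l0 * l0 + l1 * l1) / (nl * nl)
        imp_r = 1.0 - (r0 * r0 + r1 * r1) / (nr * nr)
        gains = imp_parent - (nl * imp_l + nr * imp_r) / n
        # ties within a feature (to float tolerance) -> lowest cutpoint
        i = int(np.nonzero(gains >= gains.max() - 1e-12)[0][0])
        gain = float(gains[i])
        cut = (xs[ch[i]] + xs[ch[i] + 1]) / 2.0
        # ties across features: strict '>' keeps the lower feature index
        if best is None or gain > best.gain + 1e-12:
            best = SplitRule(j, float(cut), gain, float(gain / imp_parent))
    if best is None:
        return None
    if (n / n_root) * best.gain < config.cp * imp_root:
        return None
    return best


def _majority(counts) -> int:
    # tie predicts class 0 (no risk)
    return int(counts[1] > counts[0])


def grow_tree(X, y, config: CARTConfig | None = None) -> TreeNode:
    """Recursive partitioning with the stopping rules of ``CARTConfig``."""
    config = config or CARTConfig()
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=np.int64)
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    if np.isnan(Xm).any():
        raise ValueError("missing feature values are not supported (no surrogate splits)")
    n_total = len(y)
    n1_root = int(y.sum())
    imp_root = gini((n_total - n1_root, n1_root)) if 0 < n1_root < n_total else 0.0

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        yy = y[idx]
        n1 = int(yy.sum())
        counts = (len(yy) - n1, n1)
        node = TreeNode(counts=counts, fraction=len(yy) / n_total,
                        prediction=_majority(counts))
        if depth >= config.max_depth or imp_root == 0.0:
            return node
        rule = best_split(Xm[idx], yy, config, n_root=n_total, imp_root=imp_root)
        if rule is None:
            return node
        go_left = Xm[idx, rule.feature] < rule.cutpoint
        node.split = rule
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    return build(np.arange(n_total), 0)


def predict_one(tree: TreeNode, row: np.ndarray):
    """Predicted class and the root-to-leaf path for one feature row."""
    row = np.asarray(row, dtype=float)
    if np.isnan(row).any():
        raise ValueError("missing feature value; surrogate splits are not supported")
    path = []
    node = tree
    while not node.is_leaf:
        s = node.split
        left = row[s.feature] < s.cutpoint
        path.append((s.feature, s.cutpoint, "left" if left else "right"))
        node = node.left if left else node.right
    return node.prediction, path


def predict(tree: TreeNode, X) -> np.ndarray:
    Xm, _ = _as_matrix(X)
    return np.array([predict_one(tree, Xm[i])[0] for i in range(Xm.shape[0])],
                    dtype=np.int64)


def repeated_holdout(X, y, config: CARTConfig | None = None,
                     n_reps: int = 1000, frac: float = 0.8,
                     seed=None) -> HoldoutResult:
    """Label-stratified random 80/20 holdout repeated n_reps times.

    A tree is grown on each training split and scored on the held-out
    20%; deterministic given seed.
    """
    config = config or CARTConfig()
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(seed)
    idx0 = np.nonzero(y == 0)[0]
    idx1 = np.nonzero(y == 1)[0]
    k0 = int(round(frac * len(idx0)))
    k1 = int(round(frac * len(idx1)))
    if k0 == len(idx0) or k1 == len(idx1) or min(len(idx0), len(idx1)) < 2:
        raise ValueError("not enough rows per class for non-empty stratified test sets")
    acc = np.empty(n_reps)
    for r in range(n_reps):
        p0 = rng.permutation(idx0)
        p1 = rng.permutation(idx1)
        train = np.concatenate([p0[:k0], p1[:k1]])
        test = np.concatenate([p0[k0:], p1[k1:]])
        tree = grow_tree(Xm[train], y[train], config)
        acc[r] = float(np.mean(predict(tree, Xm[test]) == y[test]))
    return HoldoutResult(n_reps=n_reps, train_fraction=frac,
                         accuracies=acc, seed=seed)


_CLASS_NAMES = {0: "No", 1: "Yes"}


def render_tree(tree: TreeNode, feature_names=None, indent: str = "  ") -> str:
    """Indented text rendering: class label, no/yes counts, percent of total."""
    lines = []

    def walk(node: TreeNode, depth: int, prefix: str):
        c0, c1 = node.counts
        tag = (f"{prefix}{_CLASS_NAMES[node.prediction]} "
               f"{c0} | {c1} | {100.0 * node.fraction:.0f}%")
        lines.append(indent * depth + tag)
        if not node.is_leaf:
            s = node.split
            name = (feature_names[s.feature] if feature_names
                    else f"f{s.feature}")
            walk(node.left, depth + 1, f"[{name} < {s.cutpoint:g}] ")
            walk(node.right, depth + 1, f"[{name} >= {s.cutpoint:g}] ")

    walk(tree, 0, "")
    return "\n".join(lines)


def _node_dict(node: TreeNode) -> dict:
    d = {
        "counts": [int(node.counts[0]), int(node.counts[1])],
        "percent": round(100.0 * node.fraction, 4),
        "class": _CLASS_NAMES[node.prediction],
    }
    if not node.is_leaf:
        d["feature"] = int(node.split.feature)
        d["cutpoint"] = node.split.cutpoint
        d["left"] = _node_dict(node.left)
        d["right"] = _node_dict(node.right)
    return d


def tree_to_json(tree: TreeNode, total_n: Optional[int] = None) -> str:
    """Lossless JSON rendering (sorted keys; round-trips byte-identically)."""
    return json.dumps(_node_dict(tree), sort_keys=True, indent=1)


def tree_from_json(s: str) -> TreeNode:
    def build(d: dict, total: float) -> TreeNode:
        counts = tuple(d["counts"])
        node = TreeNode(
            counts=counts,
            fraction=d["percent"] / 100.0,
            prediction={"No": 0, "Yes": 1}[d["class"]],
        )
        if "feature" in d:
            node.split = SplitRule(d["feature"], d["cutpoint"], float("nan"), float("nan"))
            node.left = build(d["left"], total)
            node.right = build(d["right"], total)
        return node

    d = json.loads(s)
    return build(d, sum(d["counts"]))


class CadenceBandTree:
    """Thin estimator wrapper: fit on band features, predict, render."""

    def __init__(self, config: CARTConfig | None = None):
        self.config = config or CARTConfig()
        self.tree_: Optional[TreeNode] = None
        self.feature_names_: Optional[list] = None

    def fit(self, X, y) -> "CadenceBandTree":
        _, names = _as_matrix(X)
        self.feature_names_ = names
        self.tree_ = grow_tree(X, y, self.config)
        return self

    def predict(self, X) -> np.ndarray:
        if self.tree_ is None:
            raise RuntimeError("fit before predict")
        return predict(self.tree_, X)

    def render(self) -> str:
        return render_tree(self.tree_, self.feature_names_)

    def to_json(self) -> str:
        return tree_to_json(self.tree_)
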