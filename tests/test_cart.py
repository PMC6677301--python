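"""CART on cadence bands: impurity, exhaustive-split oracle, growth,
prediction, holdout protocol and renderings."""

import numpy as np
import pandas as pd
import pytest

import cadencerisk as cr
from cadencerisk.cart import (CadenceBandTree, CARTConfig, predict_one,
                              tree_from_json, tree_to_json)
from cadencerisk.synthetic import simulate_band_rule_data


def oracle_best_split(X, y, cfg):
    """Brute-force enumeration of every (feature, midpoint) candidate."""
    Xm = np.asarray(X, float)
    y = np.asarray(y)
    n, n1 = len(y), int(y.sum())
    imp_p = cr.gini((n - n1, n1))
    cands = []
    for j in range(Xm.shape[1]):
        u = np.unique(Xm[:, j])
        for a, b in zip(u[:-1], u[1:]):
            cut = (a + b) / 2.0
            L = Xm[:, j] < cut
            nl, nr = int(L.sum()), n - int(L.sum())
            if nl < cfg.min_leaf or nr < cfg.min_leaf:
                continue
            l1 = int(y[L].sum())
            r1 = n1 - l1
            imp = (nl * cr.gini((nl - l1, l1)) + nr * cr.gini((nr - r1, r1))) / n
            cands.append((j, cut, imp_p - imp))
    if not cands:
        return None
    g = max(c[2] for c in cands)
    tied = sorted(c for c in cands if c[2] >= g - 1e-12)
    return tied[0], g


class TestGini:
    @pytest.mark.parametrize("counts,expect", [
        ((10, 0), 0.0), ((5, 5), 0.5), ((30, 10), 0.375),
    ])
    def test_closed_form(self, counts, expect):
        assert cr.gini(counts) == pytest.approx(expect)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            cr.gini((0, 0))


class TestBestSplit:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        cfg = CARTConfig(min_split=5, min_leaf=2, cp=0.0)
        for _ in range(150):
            n = int(rng.integers(6, 41))
            p = int(rng.integers(1, 5))
            X = rng.integers(0, 7, size=(n, p)).astype(float)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            got = cr.best_split(X, y, cfg)
            want = oracle_best_split(X, y, cfg)
            if want is None:
                assert got is None
                continue
            (j, cut, _), gmax = want
            assert got is not None
            assert abs(got.gain - gmax) < 1e-12
            assert (got.feature, got.cutpoint) == (j, cut)

    def test_perfect_band7_separation_splits_at_midpoint(self):
        rng = np.random.default_rng(1)
        n = 60
        band7 = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0.5, 9, n))
        X = pd.DataFrame({f"band{i}": rng.uniform(0, 40, n) for i in range(7)})
        X["band7"] = band7
        y = (band7 == 0).astype(int)
        rule = cr.best_split(X, y, CARTConfig())
        assert rule.feature == 7
        assert rule.cutpoint == pytest.approx(band7[band7 > 0].min() / 2.0)

    def test_pure_node_no_split(self):
        X = np.arange(40.0).reshape(-1, 1)
        assert cr.best_split(X, np.zeros(40, dtype=int), CARTConfig()) is None

    def test_small_node_no_split(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = np.array([0, 1] * 5)
        assert cr.best_split(X, y, CARTConfig(min_split=20)) is None


class TestGrowPredict:
    def test_separable_depth_one_pure(self):
        X = np.concatenate([np.zeros(30), np.ones(30)]).reshape(-1, 1)
        y = np.concatenate([np.zeros(30, dtype=int), np.ones(30, dtype=int)])
        tree = cr.grow_tree(X, y)
        assert not tree.is_leaf
        assert tree.left.is_leaf and tree.right.is_leaf
        assert (cr.predict(tree, X) == y).all()

    def test_constant_labels_single_leaf(self):
        X = np.random.default_rng(2).normal(size=(50, 3))
        tree = cr.grow_tree(X, np.ones(50, dtype=int))
        assert tree.is_leaf

    def test_fewer_rows_than_min_split_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = np.array([0, 1] * 5)
        assert cr.grow_tree(X, y, CARTConfig()).is_leaf

    def test_counts_conserved_at_every_node(self):
        rng = np.random.default_rng(3)
        X, y, _ = simulate_band_rule_data(400, rng)
        tree = cr.grow_tree(X, y)

        def walk(node):
            if node.is_leaf:
                return
            assert (node.left.counts[0] + node.right.counts[0] == node.counts[0])
            assert (node.left.counts[1] + node.right.counts[1] == node.counts[1])
            walk(node.left)
            walk(node.right)

        walk(tree)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        X, y, _ = simulate_band_rule_data(300, rng)
        perm = rng.permutation(len(y))
        t1 = cr.grow_tree(X, y)
        t2 = cr.grow_tree(X.iloc[perm], y[perm])
        assert tree_to_json(t1) == tree_to_json(t2)

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X, y, _ = simulate_band_rule_data(300, rng)
        cols = list(X.columns)
        perm_cols = cols[::-1]
        t1 = cr.grow_tree(X, y)
        t2 = cr.grow_tree(X[perm_cols].to_numpy(), y)

        def signature(node, names):
            if node.is_leaf:
                return ("leaf", node.counts)
            return (names[node.split.feature], round(node.split.cutpoint, 9),
                    signature(node.left, names), signature(node.right, names))

        assert signature(t1, cols) == signature(t2, perm_cols)

    def test_predict_path_and_missing_error(self):
        X = np.concatenate([np.zeros(30), np.ones(30)]).reshape(-1, 1)
        y = np.concatenate([np.zeros(30, dtype=int), np.ones(30, dtype=int)])
        tree = cr.grow_tree(X, y)
        pred, path = predict_one(tree, np.array([0.0]))
        assert pred == 0 and path[0][2] == "left"
        with pytest.raises(ValueError, match="missing"):
            predict_one(tree, np.array([np.nan]))

    def test_planted_rule_recovery(self):
        rng = np.random.default_rng(6)
        X, y, _ = simulate_band_rule_data(1500, rng)
        tree = cr.grow_tree(X, y)
        Xte, _, yt = simulate_band_rule_data(1500, rng)
        agree = np.mean(cr.predict(tree, Xte) == yt)
        assert agree >= 0.95


class TestHoldout:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X, y, _ = simulate_band_rule_data(300, rng)
        a = cr.repeated_holdout(X, y, n_reps=20, seed=5)
        b = cr.repeated_holdout(X, y, n_reps=20, seed=5)
        assert a.mean_accuracy == b.mean_accuracy

    def test_separable_data_perfect_accuracy(self):
        X = np.concatenate([np.zeros(60), np.ones(60)]).reshape(-1, 1)
        y = np.concatenate([np.zeros(60, dtype=int), np.ones(60, dtype=int)])
        res = cr.repeated_holdout(X, y, n_reps=10, seed=1)
        assert res.mean_accuracy == 1.0

    def test_stratified_splits_keep_both_classes(self):
        rng = np.random.default_rng(8)
        X, y, _ = simulate_band_rule_data(120, rng)
        res = cr.repeated_holdout(X, y, n_reps=30, seed=2)
        assert np.all(res.accuracies > 0)


class TestRendering:
    def test_single_leaf_render(self):
        tree = cr.grow_tree(np.zeros((10, 1)), np.array([0] * 6 + [1] * 4))
        assert cr.render_tree(tree) == "No 6 | 4 | 100%"

    def test_json_round_trip_byte_identical(self):
        rng = np.random.default_rng(9)
        X, y, _ = simulate_band_rule_data(300, rng)
        est = CadenceBandTree().fit(X, y)
        s1 = est.to_json()
        s2 = tree_to_json(tree_from_json(s1))
        assert s1 == s2

    def test_rendered_counts_match_tree(self):
        rng = np.random.default_rng(10)
        X, y, _ = simulate_band_rule_data(300, rng)
        tree = cr.grow_tree(X, y)
        first = cr.render_tree(tree).splitlines()[0]
        c0, c1 = tree.counts
        assert f"{c0} | {c1} | 100%" in first
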