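"""ROC machinery: curve construction, AUC-concordance identity, Youden
threshold, DeLong and bootstrap CIs, outcome and stratified tables."""

import numpy as np
import pandas as pd
import pytest

import cadencerisk as cr
from cadencerisk.roc import DegenerateOutcomeError


def concordance_oracle(cases, controls):
    return float(np.mean([(c < k) + 0.5 * (c == k) for c in cases for k in controls]))


def youden_oracle(cases, controls):
    """Exhaustive candidate search with exact integer tie-breaking."""
    v = np.concatenate([cases, controls])
    u = np.unique(v)
    mids = np.concatenate([[-np.inf], (u[1:] + u[:-1]) / 2.0, [np.inf]])
    n1, n0 = len(cases), len(controls)
    best = None
    for t in mids:
        tp = int((cases < t).sum())
        tn = int((controls >= t).sum())
        key = (tp * n0 + tn * n1, tn, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return best[1], best[0][0]


def random_dataset(rng):
    n1, n0 = rng.integers(3, 30, 2)
    cases = rng.integers(0, 15, n1).astype(float)
    controls = (rng.integers(0, 15, n0) + rng.integers(0, 4)).astype(float)
    v = np.concatenate([cases, controls])
    y = np.array([True] * n1 + [False] * n0)
    return cases, controls, v, y


class TestCurve:
    def test_separated_groups_perfect_point(self):
        v = np.array([80, 90, 100, 40, 50, 60], dtype=float)
        y = np.array([False] * 3 + [True] * 3)
        c = cr.build_roc(v, y)
        i = np.searchsorted(c.thresholds, 70.0)
        assert c.thresholds[i] == 70.0
        assert c.sensitivity[i] == 1.0 and c.specificity[i] == 1.0

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        _, _, v, y = random_dataset(rng)
        c = cr.build_roc(v, y)
        assert (c.sensitivity[0], c.specificity[0]) == (0.0, 1.0)
        assert (c.sensitivity[-1], c.specificity[-1]) == (1.0, 0.0)
        assert (np.diff(c.sensitivity) >= 0).all()
        assert (np.diff(c.specificity) <= 0).all()

    def test_identical_values_only_sentinels(self):
        v = np.array([5.0] * 6)
        y = np.array([True, False] * 3)
        c = cr.build_roc(v, y)
        assert np.isinf(c.thresholds).all()
        assert set(c.sensitivity) <= {0.0, 1.0}

    def test_pairing_invariance(self):
        rng = np.random.default_rng(1)
        _, _, v, y = random_dataset(rng)
        perm = rng.permutation(len(v))
        c1, c2 = cr.build_roc(v, y), cr.build_roc(v[perm], y[perm])
        assert np.array_equal(c1.thresholds, c2.thresholds)
        assert np.array_equal(c1.tp, c2.tp)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateOutcomeError):
            cr.build_roc(np.arange(5.0), np.array([True] * 5))


class TestAUC:
    def test_perfect_separation(self):
        v = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([True] * 3 + [False] * 3)
        assert cr.auc(cr.build_roc(v, y)) == 1.0

    def test_concordance_identity_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            cases, controls, v, y = random_dataset(rng)
            a = cr.auc(cr.build_roc(v, y))
            assert abs(a - concordance_oracle(cases, controls)) < 1e-12

    def test_null_is_half(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=4000)
        y = rng.random(4000) < 0.5
        assert abs(cr.auc(cr.build_roc(v, y)) - 0.5) < 0.05

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        for _ in range(20):
            _, _, v, y = random_dataset(rng)
            ours = cr.auc(cr.build_roc(v, y))
            assert abs(ours - (1.0 - roc_auc_score(y.astype(int), v))) < 1e-12

    def test_label_flip_maps_auc(self):
        rng = np.random.default_rng(5)
        _, _, v, y = random_dataset(rng)
        a1 = cr.auc(cr.build_roc(v, y))
        a2 = cr.auc(cr.build_roc(v, ~y))
        assert abs(a1 + a2 - 1.0) < 1e-12

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        _, _, v, y = random_dataset(rng)
        a1 = cr.auc(cr.build_roc(v, y))
        a2 = cr.auc(cr.build_roc(np.exp(0.1 * v), y))
        assert abs(a1 - a2) < 1e-12


class TestDeLong:
    def test_perfect_separation_clipped_at_one(self):
        v = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([True] * 3 + [False] * 3)
        a, lo, hi, se = cr.auc_ci_delong(v, y)
        assert hi == 1.0 and a == 1.0

    def test_duplicated_data_smaller_se(self):
        rng = np.random.default_rng(7)
        _, _, v, y = random_dataset(rng)
        _, _, _, se1 = cr.auc_ci_delong(v, y)
        _, _, _, se2 = cr.auc_ci_delong(np.tile(v, 2), np.tile(y, 2))
        assert se2 < se1

    def test_insufficient_class_counts(self):
        with pytest.raises(DegenerateOutcomeError):
            cr.auc_ci_delong(np.arange(4.0), np.array([True, False, False, False]))


class TestYouden:
    def test_separated_example(self):
        v = np.array([80, 90, 100, 40, 50, 60], dtype=float)
        y = np.array([False] * 3 + [True] * 3)
        thr, sens, spec = cr.best_threshold(cr.build_roc(v, y))
        assert thr == 70.0 and sens == 1.0 and spec == 1.0

    def test_complete_overlap_j_zero(self):
        v = np.array([5.0] * 8)
        y = np.array([True, False] * 4)
        thr, sens, spec = cr.best_threshold(cr.build_roc(v, y))
        assert sens + spec - 1.0 == 0.0
        assert np.isinf(thr)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            cases, controls, v, y = random_dataset(rng)
            c = cr.build_roc(v, y)
            thr, sens, spec = cr.best_threshold(c)
            othr, oj = youden_oracle(cases, controls)
            assert thr == othr
            got = round(sens * len(cases)) * len(controls) + \
                round(spec * len(controls)) * len(cases)
            assert got == oj


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        _, _, v, y = random_dataset(rng)
        a = cr.threshold_ci_bootstrap(v, y, B=200, seed=11)
        b = cr.threshold_ci_bootstrap(v, y, B=200, seed=11)
        assert a == b

    def test_point_mass_classes_collapse(self):
        v = np.array([10.0] * 5 + [50.0] * 5)
        y = np.array([True] * 5 + [False] * 5)
        lo, hi = cr.threshold_ci_bootstrap(v, y, B=100, seed=0)
        assert lo == hi == 30.0


class TestTables:
    def test_outcome_table_cardinality_and_counts(self, small_metrics, small_labels):
        outcomes = [f"{o}_{s}" for o in cr.ROC_OUTCOMES for s in ("low", "high")]
        tab = cr.run_outcome_roc(small_metrics, small_labels, outcomes, B=50, seed=1)
        assert len(tab) == 28  # 14 outcomes x 2 metrics
        counts = cr.label_counts(
            small_labels[small_labels["seqn"].isin(small_metrics["seqn"])])
        for _, row in tab.iterrows():
            want = counts[counts["outcome"] == row["outcome"]].iloc[0]
            assert row["n_cases"] == want["cases"]
            assert row["n_controls"] == want["controls"]

    def test_all_missing_outcome_skipped_with_warning(self, small_metrics, small_labels):
        labs = small_labels.copy()
        labs["mets_high"] = pd.array([pd.NA] * len(labs), dtype="boolean")
        with pytest.warns(UserWarning, match="mets_high"):
            tab = cr.run_outcome_roc(small_metrics, labs, ["mets_high", "bmi_low"],
                                     B=20, seed=1)
        assert set(tab["outcome"]) == {"bmi_low"}

    def test_stratified_partition_identity(self, small_cohort, small_metrics,
                                           small_labels):
        tab = cr.stratified_roc(small_metrics, small_labels,
                                small_cohort.biomarkers,
                                outcomes=("mets_low",), metric_cols=("peak30",),
                                B=20, seed=2)
        male_female = tab[tab["sex"].isin(["male", "female"])]
        combined = tab[tab["sex"] == "combined"]
        assert (male_female["n_cases"].sum() + male_female["n_controls"].sum()
                == combined["n_cases"].sum() + combined["n_controls"].sum())
        assert len(tab) <= 18

    def test_stratum_without_cases_flagged_degenerate(self, small_metrics):
        bio = pd.DataFrame({
            "seqn": small_metrics["seqn"], "age": 25, "sex": "male",
        })
        labs = pd.DataFrame({
            "seqn": small_metrics["seqn"],
            "mets_low": pd.array([False] * len(small_metrics), dtype="boolean"),
        })
        tab = cr.stratified_roc(small_metrics, labs, bio, outcomes=("mets_low",),
                                metric_cols=("peak30",), B=10, seed=3)
        sub = tab[(tab["sex"] == "male") & (tab["age_bin"] == "18-29")]
        assert bool(sub["degenerate"].iloc[0])
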