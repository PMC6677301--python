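"""ROC threshold machinery for step metrics against tri-state risk labels.

Direction is fixed by the science: lower activity predicts risk, so a
participant is classified at risk when the metric falls *below* the
threshold; metric values above the threshold classify positive health.

* candidate thresholds are midpoints between consecutive distinct observed
  values, plus -inf/+inf sentinels;
* AUC is the trapezoidal area, identical to the case-control concordance
  probability P(case < control) + 1/2 P(tie);
* the optimal threshold maximizes Youden's J = sensitivity + specificity
  - 1 (ties broken by higher specificity, then lower threshold);
* AUC confidence intervals use the DeLong structural-component variance;
* threshold confidence intervals use a stratified percentile bootstrap
  (cases and controls resampled separately).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "ROCResult",
    "AgeSexStrata",
    "DegenerateOutcomeError",
    "build_roc",
    "auc",
    "auc_ci_delong",
    "best_threshold",
    "threshold_ci_bootstrap",
    "run_outcome_roc",
    "stratified_roc",
]

DEFAULT_AGE_BINS = ((18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 85))


class DegenerateOutcomeError(ValueError):
    """Raised when an outcome has no cases or no controls."""


@dataclass
class ROCCurve:
    thresholds: np.ndarray   # ascending, with -inf/+inf sentinels
    sensitivity: np.ndarray  # P(case < t)
    specificity: np.ndarray  # P(control >= t)
    n_cases: int
    n_controls: int
    # integer confusion counts at each candidate, for exact tie-breaking
    tp: np.ndarray
    tn: np.ndarray


@dataclass
class ROCResult:
    outcome: str
    metric: str
    auc: float
    auc_lo: float
    auc_hi: float
    threshold: float
    thr_lo: float
    thr_hi: float
    sensitivity: float
    specificity: float
    n_controls: int
    n_cases: int
    degenerate: bool = False


@dataclass
class AgeSexStrata:
    age_bins: tuple = DEFAULT_AGE_BINS
    sexes: tuple = ("male", "female", "combined")


def _split(values, labels):
    v = np.asarray(values, dtype=float)
    y = pd.array(labels, dtype="boolean") if not hasattr(labels, "dtype") else labels
    y = pd.Series(y)
    keep = y.notna().to_numpy() & np.isfinite(v)
    v = v[keep]
    yy = y[keep].astype(bool).to_numpy()
    return v[yy], v[~yy]  # cases, controls


def build_roc(values, labels) -> ROCCurve:
    """Confusion counts at every candidate threshold (risk iff value < t)."""
    cases, controls = _split(values, labels)
    if len(cases) == 0 or len(controls) == 0:
        raise DegenerateOutcomeError(
            f"need both classes: {len(cases)} cases, {len(controls)} controls"
        )
    u = np.unique(np.concatenate([cases, controls]))
    mids = (u[1:] + u[:-1]) / 2.0 if len(u) > 1 else np.empty(0)
    thr = np.concatenate([[-np.inf], mids, [np.inf]])
    cases_s = np.sort(cases)
    controls_s = np.sort(controls)
    tp = np.searchsorted(cases_s, thr, side="left")      # cases strictly below t
    fp = np.searchsorted(controls_s, thr, side="left")   # controls strictly below t
    tn = len(controls) - fp
    return ROCCurve(
        thresholds=thr,
        sensitivity=tp / len(cases),
        specificity=tn / len(controls),
        n_cases=len(cases),
        n_controls=len(controls),
        tp=tp.astype(np.int64),
        tn=tn.astype(np.int64),
    )


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area over (1 - specificity, sensitivity)."""
    fpr = 1.0 - curve.specificity
    return float(np.trapezoid(curve.sensitivity, fpr))


def _delong_components(cases, controls):
    """Placement values: for each case, the fraction of controls above it
    (ties count 1/2), and symmetrically for controls."""
    cs = np.sort(controls)
    above = len(controls) - np.searchsorted(cs, cases, side="right")
    ties = np.searchsorted(cs, cases, side="right") - np.searchsorted(cs, cases, side="left")
    v10 = (above + 0.5 * ties) / len(controls)
    ks = np.sort(cases)
    below = np.searchsorted(ks, controls, side="left")
    ties_c = np.searchsorted(ks, controls, side="right") - below
    v01 = (below + 0.5 * ties_c) / len(cases)
    return v10, v01


def auc_ci_delong(values, labels, level: float = 0.95):
    """DeLong 95% CI for the AUC, clipped to [0, 1].

    Returns (auc, lo, hi, se).
    """
    from scipy.stats import norm
    cases, controls = _split(values, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise DegenerateOutcomeError("DeLong CI needs >= 2 cases and >= 2 controls")
    v10, v01 = _delong_components(cases, controls)
    a = v10.mean()  # == concordance P(case < control) + 1/2 ties
    var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls)
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + level / 2.0)
    return float(a), float(np.clip(a - z * se, 0, 1)), float(np.clip(a + z * se, 0, 1)), se


def best_threshold(curve: ROCCurve):
    """Youden-optimal candidate threshold.

    Maximizes J = sensitivity + specificity - 1 using exact integer
    arithmetic (J * n1 * n0 = tp*n0 + tn*n1 - n1*n0); ties are broken by
    higher specificity, then lower threshold.  Returns
    (threshold, sensitivity, specificity).
    """
    n1, n0 = curve.n_cases, curve.n_controls
    j_scaled = curve.tp * n0 + curve.tn * n1 - n1 * n0
    best = j_scaled.max()
    idx = np.nonzero(j_scaled == best)[0]
    if len(idx) > 1:
        spec_best = curve.tn[idx].max()
        idx = idx[curve.tn[idx] == spec_best]
    i = idx[0]  # thresholds ascending -> lowest threshold first
    return float(curve.thresholds[i]), float(curve.sensitivity[i]), float(curve.specificity[i])


def threshold_ci_bootstrap(values, labels, B: int = 2000, seed=None, level: float = 0.95):
    """Stratified percentile bootstrap CI for the Youden threshold.

    Cases and controls are resampled separately; deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    cases, controls = _split(values, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise DegenerateOutcomeError("bootstrap CI needs >= 2 per class")
    n1, n0 = len(cases), len(controls)
    thrs = np.empty(B)
    y_boot = np.concatenate([np.ones(n1, dtype=bool), np.zeros(n0, dtype=bool)])
    for b in range(B):
        vb = np.concatenate([
            cases[rng.integers(0, n1, n1)],
            controls[rng.integers(0, n0, n0)],
        ])
        thrs[b] = best_threshold(build_roc(vb, y_boot))[0]
    alpha = (1.0 - level) / 2.0
    finite = thrs[np.isfinite(thrs)]
    if len(finite) == 0:
        return float("nan"), float("nan")
    lo, hi = np.percentile(finite, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def _one_roc(values, labels, outcome: str, metric: str, B: int, seed) -> ROCResult:
    curve = build_roc(values, labels)
    a, lo, hi, _ = auc_ci_delong(values, labels)
    thr, sens, spec = best_threshold(curve)
    tlo, thi = threshold_ci_bootstrap(values, labels, B=B, seed=seed)
    return ROCResult(
        outcome=outcome, metric=metric, auc=a, auc_lo=lo, auc_hi=hi,
        threshold=thr, thr_lo=tlo, thr_hi=thi, sensitivity=sens,
        specificity=spec, n_controls=curve.n_controls, n_cases=curve.n_cases,
    )


def run_outcome_roc(metrics: pd.DataFrame, labels: pd.DataFrame,
                    outcomes, metric_cols=("peak30", "steps_per_day"),
                    B: int = 2000, seed=None) -> pd.DataFrame:
    """One ROCResult row per (outcome, metric), joined on seqn.

    Outcomes with a missing class are skipped with a warning.  Bootstrap
    seeds are derived per row from ``seed`` so row order is irrelevant.
    """
    merged = metrics.merge(labels, on="seqn", how="inner", validate="one_to_one")
    unmatched = set(labels["seqn"]) - set(metrics["seqn"])
    rows = []
    ss = np.random.SeedSequence(seed)
    for i, outcome in enumerate(outcomes):
        if outcome not in merged.columns:
            raise KeyError(f"label column {outcome!r} not found")
        for j, m in enumerate(metric_cols):
            child = np.random.SeedSequence(entropy=ss.entropy or 0,
                                           spawn_key=(i, j)).generate_state(1)[0]
            try:
                rows.append(_one_roc(merged[m], merged[outcome], outcome, m,
                                     B, int(child)))
            except DegenerateOutcomeError as e:
                warnings.warn(f"skipping {outcome}/{m}: {e}")
                logger.warning("skipping %s/%s: %s", outcome, m, e)
    out = pd.DataFrame([r.__dict__ for r in rows])
    if unmatched:
        logger.info("%d labelled participants had no metrics", len(unmatched))
    return out


def stratified_roc(metrics: pd.DataFrame, labels: pd.DataFrame,
                   biomarkers: pd.DataFrame, outcomes=("mets_low", "mets_high"),
                   metric_cols=("peak30", "steps_per_day"),
                   strata: AgeSexStrata | None = None,
                   B: int = 500, seed=None) -> pd.DataFrame:
    """Sex- and age-decade-specific ROC results for the given outcomes.

    Strata with a missing class are reported as degenerate rows (NaN
    estimates) rather than being fatal.
    """
    strata = strata or AgeSexStrata()
    demo = biomarkers[["seqn", "age", "sex"]]
    merged = metrics.merge(labels, on="seqn").merge(demo, on="seqn")
    rows = []
    ss = np.random.SeedSequence(seed)
    k = 0
    for sex in strata.sexes:
        sub_sex = merged if sex == "combined" else merged[
            merged["sex"].astype(str).str.lower() == sex
        ]
        for (a0, a1) in strata.age_bins:
            sub = sub_sex[(sub_sex["age"] >= a0) & (sub_sex["age"] <= a1)]
            for outcome in outcomes:
                for m in metric_cols:
                    k += 1
                    child = np.random.SeedSequence(entropy=ss.entropy or 0,
                                                   spawn_key=(k,)).generate_state(1)[0]
                    base = {"sex": sex, "age_bin": f"{a0}-{a1}",
                            "outcome": outcome, "metric": m}
                    try:
                        r = _one_roc(sub[m], sub[outcome], outcome, m, B, int(child))
                        rows.append({**base, **{f: getattr(r, f) for f in (
                            "auc", "auc_lo", "auc_hi", "threshold", "thr_lo",
                            "thr_hi", "sensitivity", "specificity",
                            "n_controls", "n_cases")}, "degenerate": False})
                    except DegenerateOutcomeError:
                        lab = sub[outcome]
                        rows.append({**base, "auc": np.nan, "auc_lo": np.nan,
                                     "auc_hi": np.nan, "threshold": np.nan,
                                     "thr_lo": np.nan, "thr_hi": np.nan,
                                     "sensitivity": np.nan, "specificity": np.nan,
                                     "n_controls": int((lab == False).sum()),  # noqa: E712
                                     "n_cases": int((lab == True).sum()),      # noqa: E712
                                     "degenerate": True})
    return pd.DataFrame(rows)
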