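"""Design-weighted logistic regression with Taylor-linearized variances.

The model is the pseudo-maximum-likelihood logistic fit for a complex
survey (stratified, clustered, weighted) design: coefficients maximize the
weighted Bernoulli log-likelihood

    l(b) = sum_i w_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],
    p_i = expit(x_i' b),

via iteratively reweighted least squares, and the covariance is the
linearization sandwich B^-1 V B^-1 with B the weighted information and V
the with-replacement between-PSU variance of the weighted score totals
within strata:

    V = sum_h n_h / (n_h - 1) * sum_i (z_hi - zbar_h)(z_hi - zbar_h)',

z_hi the summed weighted scores of PSU i in stratum h.

Odds ratios are reported per s-unit exposure change (s = 20 steps/min for
peak 30-min cadence, 1000 for steps/day): OR = e^{s b} with CI
e^{s b +/- 1.96 s SE(b)}.  Model ranking uses a pseudo-AIC
(-2 * weighted pseudo-log-likelihood with weights rescaled to mean 1, plus
2k); it is a ranking device at fixed design, not a design-based AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SurveyDesign",
    "LogitModelSpec",
    "ORResult",
    "SurveyLogit",
    "SurveyLogitResults",
    "ConvergenceError",
    "fit_weighted_logit",
    "model_aic_compare",
    "logit_linearity_check",
    "LinearityReport",
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge (e.g. perfect separation)."""


@dataclass
class SurveyDesign:
    """Per-observation sampling weight, stratum id and PSU id."""

    weights: np.ndarray
    strata: np.ndarray
    psu: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.strata = np.asarray(self.strata)
        self.psu = np.asarray(self.psu)
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive and finite")
        if not (len(self.weights) == len(self.strata) == len(self.psu)):
            raise ValueError("design arrays must have equal length")

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(self.weights[mask], self.strata[mask], self.psu[mask])

    def validate_psu_counts(self) -> None:
        df = pd.DataFrame({"h": self.strata, "p": self.psu})
        n_psu = df.groupby("h")["p"].nunique()
        bad = n_psu[n_psu < 2]
        if len(bad):
            raise ValueError(
                "linearized variance needs >= 2 PSUs per stratum; "
                f"offending strata: {list(bad.index)}"
            )


@dataclass
class LogitModelSpec:
    outcome: str
    exposure: str                      # 'peak30' or 'steps_per_day'
    adjusters: tuple = ()              # subset of ('age', 'smoking')
    scale: float = None                # OR reporting scale

    def __post_init__(self):
        if self.scale is None:
            self.scale = 20.0 if self.exposure == "peak30" else 1000.0
        if self.scale <= 0:
            raise ValueError("exposure scale must be > 0")


@dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    scale: float
    term: str
    direction_note: str = (
        "OR is reported as e^{scale * beta} with beta's fitted sign: values "
        "below 1 mean risk decreases per scale-unit *increase* in exposure."
    )


class SurveyLogit:
    """Pseudo-ML logistic model for a complex survey design.

    Parameters
    ----------
    endog : (n,) 0/1 outcome
    exog : (n, k) design matrix including the intercept column
    design : SurveyDesign
    exog_names : optional column names for reporting
    """

    def __init__(self, endog, exog, design: SurveyDesign,
                 exog_names: Optional[Sequence[str]] = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.design = design
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog/exog length mismatch")
        if not np.all(np.isin(self.endog, (0.0, 1.0))):
            raise ValueError("endog must be binary 0/1")
        if self.endog.min() == self.endog.max():
            raise ValueError("degenerate outcome: all responses identical")

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "SurveyLogitResults":
        X, y, w = self.exog, self.endog, self.design.weights
        k = X.shape[1]
        beta = np.zeros(k)
        for it in range(maxiter):
            eta = X @ beta
            p = expit(eta)
            pq = np.clip(p * (1 - p), 1e-12, None)
            W = w * pq
            z = eta + (y - p) / pq
            XtW = X.T * W
            try:
                new = np.linalg.solve(XtW @ X, XtW @ z)
            except np.linalg.LinAlgError as e:
                raise ConvergenceError(f"singular information matrix: {e}") from e
            step = np.max(np.abs(new - beta))
            beta = new
            if step < tol:
                break
        else:
            raise ConvergenceError(
                f"IRLS did not converge in {maxiter} iterations "
                f"(last step {step:.3g}); possible perfect separation"
            )
        eta = X @ beta
        if np.max(np.abs(eta)) > 30:
            raise ConvergenceError(
                "fitted linear predictor diverged (|eta| > 30); "
                "perfect or quasi-perfect separation"
            )
        p = expit(eta)
        llf = float(np.sum(w * (y * np.log(np.clip(p, 1e-300, None))
                                + (1 - y) * np.log(np.clip(1 - p, 1e-300, None)))))
        w1 = w / w.mean()
        llf_scaled = float(np.sum(w1 * (y * np.log(np.clip(p, 1e-300, None))
                                        + (1 - y) * np.log(np.clip(1 - p, 1e-300, None)))))
        cov = _linearized_cov(X, y, w, beta, self.design)
        return SurveyLogitResults(self, beta, cov, llf, llf_scaled, it + 1)


def _linearized_cov(X, y, w, beta, design: SurveyDesign) -> np.ndarray:
    """Sandwich B^-1 V B^-1 with between-PSU score variance within strata."""
    design.validate_psu_counts()
    p = expit(X @ beta)
    pq = np.clip(p * (1 - p), 1e-12, None)
    B = (X.T * (w * pq)) @ X                     # weighted information
    scores = (w * (y - p))[:, None] * X          # weighted score contributions
    df = pd.DataFrame(scores)
    df["_h"] = design.strata
    df["_p"] = design.psu
    z = df.groupby(["_h", "_p"], sort=True).sum() # PSU totals z_hi
    k = X.shape[1]
    V = np.zeros((k, k))
    for h, zh in z.groupby(level=0, sort=True):
        n_h = len(zh)
        d = zh.to_numpy() - zh.to_numpy().mean(axis=0)
        V += n_h / (n_h - 1) * d.T @ d
    Binv = np.linalg.inv(B)
    cov = Binv @ V @ Binv
    return (cov + cov.T) / 2.0


class SurveyLogitResults:
    """Estimates, linearized covariance and derived quantities."""

    def __init__(self, model: SurveyLogit, params, cov_params, llf, llf_scaled, n_iter):
        self.model = model
        self.params = np.asarray(params)
        self.cov_params = np.asarray(cov_params)
        self.bse = np.sqrt(np.diag(self.cov_params))
        self.llf = llf
        self._llf_scaled = llf_scaled
        self.n_iter = n_iter
        self.nobs = len(model.endog)

    @property
    def aic(self) -> float:
        """Pseudo-AIC: -2 * (mean-1-weight pseudo-log-likelihood) + 2k."""
        return -2.0 * self._llf_scaled + 2.0 * len(self.params)

    def zvalues(self):
        return self.params / self.bse

    def pvalues(self):
        z = self.zvalues()
        return 2.0 * norm.sf(np.abs(z))

    def conf_int(self, level: float = 0.95):
        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def odds_ratio(self, term: str, scale: float) -> ORResult:
        """Scaled odds ratio e^{s b} with CI e^{s b +/- 1.96 s SE(b)}."""
        i = self.model.exog_names.index(term)
        b, se = self.params[i], self.bse[i]
        z = norm.ppf(0.975)
        return ORResult(
            odds_ratio=float(np.exp(scale * b)),
            ci_low=float(np.exp(scale * b - z * scale * se)),
            ci_high=float(np.exp(scale * b + z * scale * se)),
            scale=scale,
            term=term,
        )

    def summary(self) -> str:
        lines = [
            "Survey-weighted logistic regression (pseudo-ML, linearized SEs)",
            f"n = {self.nobs}    pseudo-AIC = {self.aic:.3f}    iterations = {self.n_iter}",
            f"{'term':>12} {'coef':>12} {'lin. SE':>10} {'z':>8} {'P>|z|':>8}",
        ]
        ci = self.conf_int()
        for name, b, se, zv, p, (lo, hi) in zip(
            self.model.exog_names, self.params, self.bse,
            self.zvalues(), self.pvalues(), ci
        ):
            lines.append(f"{name:>12} {b:>12.6f} {se:>10.6f} {zv:>8.3f} {p:>8.4f}"
                         f"   [{lo:.6f}, {hi:.6f}]")
        return "\n".join(lines)


def _build_matrix(data: pd.DataFrame, spec: LogitModelSpec):
    cols = [spec.exposure, *spec.adjusters]
    y = data[spec.outcome]
    y = pd.Series(pd.array(y, dtype="boolean")) if y.dtype == object else y
    mask = pd.Series(y).notna().to_numpy()
    for c in cols:
        mask &= pd.to_numeric(data[c], errors="coerce").notna().to_numpy()
    sub = data.loc[mask]
    X = np.column_stack([np.ones(mask.sum())] +
                        [pd.to_numeric(sub[c]).to_numpy(dtype=float) for c in cols])
    yv = pd.Series(sub[spec.outcome]).astype("boolean").astype(bool).to_numpy().astype(float)
    names = ["const", *cols]
    return yv, X, names, mask


def fit_weighted_logit(data: pd.DataFrame, design: SurveyDesign,
                       spec: LogitModelSpec) -> SurveyLogitResults:
    """Build the design matrix from named columns, drop missing, fit."""
    y, X, names, mask = _build_matrix(data, spec)
    model = SurveyLogit(y, X, design.subset(mask), exog_names=names)
    return model.fit()


def model_aic_compare(data: pd.DataFrame, design: SurveyDesign,
                      specs: Sequence[LogitModelSpec]):
    """Fit all specs on the identical row set; return fits sorted by pseudo-AIC.

    Raises if the specs imply different analysis rows (AICs would not be
    comparable).
    """
    masks = [_build_matrix(data, s)[3] for s in specs]
    common = masks[0]
    for m in masks[1:]:
        if not np.array_equal(m, common):
            raise ValueError("specs select different analysis rows; "
                             "restrict to a common complete-case set first")
    fits = [(s, fit_weighted_logit(data, design, s)) for s in specs]
    return sorted(fits, key=lambda t: t[1].aic)


@dataclass
class LinearityReport:
    bin_table: pd.DataFrame       # exposure bin midpoints and empirical logits
    quad_coef: float
    quad_p: float
    flagged: bool                 # nonlinearity at p < 0.05
    n_bins_used: int
    notes: list = field(default_factory=list)


def logit_linearity_check(data: pd.DataFrame, design: SurveyDesign,
                          spec: LogitModelSpec, bins: int = 10) -> LinearityReport:
    """Diagnostic for logit-linearity in a continuous exposure.

    Empirical logits within exposure quantile bins (with a 0.5 continuity
    correction), plus a design-based Wald test of an added quadratic
    exposure term.
    """
    y, X, names, mask = _build_matrix(data, spec)
    x = X[:, 1]
    notes = []
    qs = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
    if len(qs) - 1 < bins:
        notes.append(f"reduced to {len(qs) - 1} bins (ties in exposure)")
    bin_idx = np.clip(np.searchsorted(qs, x, side="right") - 1, 0, len(qs) - 2)
    rows = []
    for b in range(len(qs) - 1):
        m = bin_idx == b
        if m.sum() == 0:
            continue
        k1, n = y[m].sum(), m.sum()
        rows.append({
            "bin": b, "x_mid": float(x[m].mean()), "n": int(n),
            "events": int(k1),
            "emp_logit": float(np.log((k1 + 0.5) / (n - k1 + 0.5))),
        })
    both = sum(1 for r in rows if 0 < r["events"] < r["n"])
    if both < 3:
        warnings.warn("fewer than 3 bins contain both classes; "
                      "linearity diagnostic is unreliable")
        notes.append("fewer than 3 informative bins")

    xc = x - x.mean()  # centre to tame collinearity of x and x^2
    Xq = np.column_stack([X, xc ** 2])
    model = SurveyLogit(y, Xq, design.subset(mask),
                        exog_names=[*names, f"{spec.exposure}^2"])
    res = model.fit()
    b_q = res.params[-1]
    p_q = float(2.0 * norm.sf(abs(b_q / res.bse[-1])))
    return LinearityReport(
        bin_table=pd.DataFrame(rows),
        quad_coef=float(b_q),
        quad_p=p_q,
        flagged=p_q < 0.05,
        n_bins_used=len(rows),
        notes=notes,
    )
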