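"""Synthetic NHANES-like cohort generator.

Emulates the structure of a minute-epoch physical-activity-monitor study:
each participant wears a hip accelerometer for a week, producing 1440
one-minute records per day (activity counts and step counts), alongside a
single examination/laboratory record (biomarkers, demographics) and complex
survey design variables (stratum, PSU, sampling weight).

Every distributional choice is a stand-in calibrated to published summary
moments of the 2005-2006 national accelerometer sample (male steps/day
~6933, male peak 30-min cadence ~70 steps/min); the generator's purpose is
to provide cohorts with *known* generative parameters so that wear-time QC,
step metrics, risk labelling, ROC thresholds, weighted logistic fits and
cadence-band trees can all be tested for parameter recovery.

Ground truth (latent activity levels, per-outcome risk states and
probabilities, injected artifact counts) is retained in
``SyntheticCohort.truth`` and never written to the public CSV outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

__all__ = [
    "WearModel",
    "ActivityModel",
    "ArtifactModel",
    "RiskOutcomeModel",
    "FactorValueModel",
    "DesignModel",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "default_nhanes_like_config",
    "solve_intercept",
    "equal_j_cutpoint",
    "simulate_peak30_risk",
    "simulate_survey_logit",
    "simulate_band_rule_data",
]

MINUTES_PER_DAY = 1440

# Factor cutpoints used to place biomarker values consistently with the
# latent risk states (mirrors the default risk-threshold table).
_FACTOR_CUTS = {
    # factor: (direction, {sex: (low_cut, high_cut)}, (support_lo, support_hi))
    "bmi": ("ge", {"male": (25.0, 30.0), "female": (25.0, 30.0)}, (14.0, 60.0)),
    "waist": ("ge", {"male": (94.0, 102.0), "female": (80.0, 88.0)}, (55.0, 160.0)),
    "sbp": ("ge", {"male": (120.0, 130.0), "female": (120.0, 130.0)}, (80.0, 220.0)),
    "dbp": ("ge", {"male": (80.0, 85.0), "female": (80.0, 85.0)}, (40.0, 130.0)),
    "tg": ("ge", {"male": (150.0, 200.0), "female": (150.0, 200.0)}, (30.0, 900.0)),
    "hdl": ("le", {"male": (59.0, 40.0), "female": (59.0, 40.0)}, (10.0, 130.0)),
    "glucose": ("ge", {"male": (100.0, 126.0), "female": (100.0, 126.0)}, (55.0, 350.0)),
}

FACTORS = tuple(_FACTOR_CUTS)


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass
class WearModel:
    """Daily wear/non-wear run structure.

    Wear starts at a fixed clock minute and lasts a fixed duration; all
    minutes outside the wear window are emitted as zero-count, zero-step
    records.  With probability ``p_midday_nonwear_run`` a day additionally
    contains one mid-wear non-wear run (device taken off), and with
    probability ``p_skip_day`` the whole day is zero (device not worn).
    """

    wear_start_minute: int = 420        # 07:00
    wear_duration_minutes: int = 840    # 14 h, ends 21:00
    p_midday_nonwear_run: float = 0.30
    nonwear_run_length: int = 90
    p_skip_day: float = 0.08


@dataclass
class ActivityModel:
    """Hurdle model for minute cadence.

    Each wear minute is a stepping minute with participant-specific
    probability; stepping minutes draw cadence from a truncated normal on
    [1, 180] steps/min.  Activity counts follow counts = steps x
    counts_per_step + noise for stepping minutes (floored so that organic
    stepping minutes always carry >= 500 counts; sub-500-count stepping is
    modelled explicitly by the artifact channel), and a zero-inflated
    Poisson for non-stepping wear minutes.
    """

    p_step_minute: float = 0.16
    p_step_logit_sd: float = 0.55       # between-person heterogeneity
    cadence_mean: float = 45.0
    cadence_between_sd: float = 8.0
    cadence_sd: float = 15.0            # within-person, minute to minute
    counts_per_step_mean: float = 30.0
    counts_per_step_sd: float = 5.0
    counts_noise_sd: float = 80.0
    nonstep_counts_mean: float = 40.0
    nonstep_zero_prob: float = 0.25
    female_p_step_logit_shift: float = -0.22
    female_cadence_shift: float = -2.5


@dataclass
class ArtifactModel:
    """Device artifact channels injected into wear minutes.

    ``p_lowcount_step_minute``: stepping registered at implausibly low
    intensity (< 500 counts/min), the kind of minute the step censor is
    meant to remove.  ``p_spike_minute``: cadence spikes above 180
    steps/min.  ``p_unreliable_minute`` / ``p_uncalibrated_participant``:
    PAXSTAT/PAXCAL-style quality flags.
    """

    p_lowcount_step_minute: float = 0.002
    p_spike_minute: float = 0.0005
    spike_cadence_range: tuple[int, int] = (181, 250)
    p_unreliable_minute: float = 0.002
    p_uncalibrated_participant: float = 0.01


@dataclass
class RiskOutcomeModel:
    """Logistic model for one binary risk state.

    P(at risk) = expit(alpha + b_peak30 * peak30 + b_age * age +
    b_smoking * smoking).  If ``intercept`` is None the intercept is solved
    at generation time so the cohort's expected prevalence equals
    ``prevalence`` exactly (recorded in the truth table).
    """

    prevalence: Optional[float] = None
    intercept: Optional[float] = None
    beta_peak30: float = -0.03          # per steps/min
    beta_age: float = 0.02              # per year
    beta_smoking: float = 0.30

    def __post_init__(self):
        if (self.prevalence is None) == (self.intercept is None):
            raise ConfigurationError(
                "risk_model: exactly one of prevalence/intercept must be set"
            )
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("risk_model.prevalence must be in (0,1)")


def _default_risk_model() -> dict:
    # Target prevalences per (factor, severity); low-risk always at least as
    # prevalent as high-risk, mirroring the nesting of paired cutpoints.
    prevs = {
        "bmi": (0.65, 0.33),
        "waist": (0.70, 0.37),
        "sbp": (0.50, 0.30),
        "dbp": (0.35, 0.15),
        "tg": (0.32, 0.19),
        "hdl": (0.63, 0.18),
        "glucose": (0.45, 0.10),
    }
    out = {}
    for fac, (p_lo, p_hi) in prevs.items():
        out[(fac, "low")] = RiskOutcomeModel(prevalence=p_lo)
        out[(fac, "high")] = RiskOutcomeModel(prevalence=p_hi)
    return out


@dataclass
class FactorValueModel:
    """Biomarker value distribution conditional on latent risk region.

    Values are drawn from a normal truncated to the region implied by the
    risk state (safe / low-only / high), with the region mean placed
    ``offset`` units beyond the defining cutpoint and the mid region
    centred between the two cutpoints.
    """

    offset: float
    sd: float
    p_missing: float = 0.0


def _default_biomarker_model() -> dict:
    return {
        "bmi": FactorValueModel(3.0, 2.5, 0.02),
        "waist": FactorValueModel(8.0, 6.0, 0.05),
        "sbp": FactorValueModel(8.0, 8.0, 0.08),
        "dbp": FactorValueModel(5.0, 5.0, 0.08),
        "tg": FactorValueModel(60.0, 40.0, 0.35),
        "hdl": FactorValueModel(8.0, 6.0, 0.10),
        "glucose": FactorValueModel(12.0, 10.0, 0.35),
    }


@dataclass
class DesignModel:
    """Complex survey design: stratified two-stage sample with lognormal
    weights normalized to sum to n.  At least two PSUs per stratum so the
    linearized (between-PSU) variance is estimable."""

    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_sigma: float = 0.5


@dataclass
class GeneratorConfig:
    n_participants: int = 200
    n_days: int = 7
    seed: int = 0
    wear_model: WearModel = field(default_factory=WearModel)
    activity_model: ActivityModel = field(default_factory=ActivityModel)
    artifact_model: ArtifactModel = field(default_factory=ArtifactModel)
    risk_model: dict = field(default_factory=_default_risk_model)
    biomarker_model: dict = field(default_factory=_default_biomarker_model)
    design_model: DesignModel = field(default_factory=DesignModel)
    age_range: tuple[int, int] = (18, 85)
    p_female: float = 0.5
    p_smoking: float = 0.22

    def validate(self) -> None:
        a, w, f = self.activity_model, self.wear_model, self.artifact_model
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        for name, p in [
            ("wear_model.p_midday_nonwear_run", w.p_midday_nonwear_run),
            ("wear_model.p_skip_day", w.p_skip_day),
            ("activity_model.p_step_minute", a.p_step_minute),
            ("activity_model.nonstep_zero_prob", a.nonstep_zero_prob),
            ("artifact_model.p_lowcount_step_minute", f.p_lowcount_step_minute),
            ("artifact_model.p_spike_minute", f.p_spike_minute),
            ("artifact_model.p_unreliable_minute", f.p_unreliable_minute),
            ("artifact_model.p_uncalibrated_participant", f.p_uncalibrated_participant),
            ("p_female", self.p_female),
            ("p_smoking", self.p_smoking),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        for name, s in [
            ("activity_model.cadence_sd", a.cadence_sd),
            ("activity_model.counts_per_step_sd", a.counts_per_step_sd),
        ]:
            if s <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {s}")
        if f.spike_cadence_range[0] <= 180:
            raise ConfigurationError(
                "artifact_model.spike_cadence_range lower bound must be > 180"
            )
        if not 0 <= w.wear_start_minute < MINUTES_PER_DAY:
            raise ConfigurationError("wear_model.wear_start_minute out of range")
        if w.wear_start_minute + w.wear_duration_minutes > MINUTES_PER_DAY:
            raise ConfigurationError("wear window must fit within the day")
        if self.design_model.psus_per_stratum < 2:
            raise ConfigurationError("design_model.psus_per_stratum must be >= 2")
        n_units = self.design_model.n_strata * self.design_model.psus_per_stratum
        if self.n_participants < 2 * n_units:
            raise ConfigurationError(
                "n_participants too small for the survey design "
                f"(need >= {2 * n_units} for {n_units} PSUs)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["risk_model"] = {
            f"{fac}_{sev}": asdict(m) for (fac, sev), m in self.risk_model.items()
        }
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort: public minute/biomarker tables plus ground truth."""

    minutes: pd.DataFrame       # seqn, day, minute, counts, steps, paxstat, paxcal
    biomarkers: pd.DataFrame    # seqn, age, sex, smoking, <factors>, weight, stratum, psu
    truth: dict                 # config, per-participant latents/risk states, artifact counts


def solve_intercept(target_prevalence: float, linear_predictor: np.ndarray) -> float:
    """Intercept alpha such that mean(expit(alpha + lp)) == target exactly.

    Solved by bisection on the (monotone) mean response; used to calibrate
    risk-model intercepts against a realized covariate sample.
    """
    lp = np.asarray(linear_predictor, dtype=float)

    def f(a):
        return expit(a + lp).mean() - target_prevalence

    lo, hi = -40.0, 40.0
    return brentq(f, lo, hi, xtol=1e-12)


def equal_j_cutpoint(alpha: float, beta: float, x_sample: np.ndarray) -> float:
    """Population Youden-optimal cutpoint for a pure logistic link.

    For P(risk | X=x) = expit(alpha + beta*x), Youden's J(t) =
    P(X<t | risk) - P(X<t | no risk) is stationary where the conditional
    risk equals the marginal prevalence, i.e. at
    t* = (logit(pbar) - alpha) / beta.
    """
    if beta == 0:
        raise ValueError("beta must be nonzero")
    pbar = expit(alpha + beta * np.asarray(x_sample, dtype=float)).mean()
    return float((logit(pbar) - alpha) / beta)


def _trunc_normal(rng, lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _participant_frame(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    dm = config.design_model
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    smoking = (rng.random(n) < config.p_smoking).astype(np.int64)

    # Balanced random assignment to strata/PSUs guarantees >= 2 PSUs
    # per stratum for the linearized variance.
    order = rng.permutation(n)
    stratum = np.empty(n, dtype=np.int64)
    psu = np.empty(n, dtype=np.int64)
    stratum[order] = (np.arange(n) % dm.n_strata) + 1
    psu[order] = ((np.arange(n) // dm.n_strata) % dm.psus_per_stratum) + 1

    weight = rng.lognormal(mean=0.0, sigma=dm.weight_sigma, size=n)
    weight *= n / weight.sum()

    am = config.activity_model
    a_latent = rng.normal(size=n)  # shared activity latent: active people step more & faster
    lp_step = logit(am.p_step_minute) + am.p_step_logit_sd * a_latent
    lp_step += np.where(sex == "female", am.female_p_step_logit_shift, 0.0)
    p_step = expit(lp_step)
    cad_mean = (
        am.cadence_mean
        + am.cadence_between_sd * (0.6 * a_latent + 0.8 * rng.normal(size=n))
        + np.where(sex == "female", am.female_cadence_shift, 0.0)
    )
    cad_mean = np.clip(cad_mean, 15.0, 140.0)

    return pd.DataFrame(
        {
            "seqn": np.arange(1, n + 1, dtype=np.int64),
            "sex": sex,
            "age": age,
            "smoking": smoking,
            "weight": weight,
            "stratum": stratum,
            "psu": psu,
            "p_step": p_step,
            "cadence_mean": cad_mean,
        }
    )


def _generate_minutes(config: GeneratorConfig, part: pd.DataFrame,
                      rng: np.random.Generator):
    """Dense (participant-day x 1440) step/count matrices plus flags.

    Returns (steps, counts, reliable, calibrated, clean_steps) where
    clean_steps is the artifact-free, censor-applied step matrix used to
    define latent peak30/steps-day truth.
    """
    n, d = config.n_participants, config.n_days
    wm, am, fm = config.wear_model, config.activity_model, config.artifact_model
    nd = n * d

    wear = np.zeros((nd, MINUTES_PER_DAY), dtype=bool)
    w0, w1 = wm.wear_start_minute, wm.wear_start_minute + wm.wear_duration_minutes
    wear[:, w0:w1] = True

    skip = rng.random(nd) < wm.p_skip_day
    wear[skip, :] = False

    midday = (rng.random(nd) < wm.p_midday_nonwear_run) & ~skip
    run_len = wm.nonwear_run_length
    lo = w0 + 30
    hi = max(lo + 1, w1 - 30 - run_len)
    starts = rng.integers(lo, hi, size=nd)
    idx = np.nonzero(midday)[0]
    for i in idx:  # few per cohort; fine as a loop
        wear[i, starts[i]:starts[i] + run_len] = False

    # hurdle: stepping minutes and their cadence
    p_step = np.repeat(part["p_step"].to_numpy(), d)[:, None]
    stepping = wear & (rng.random((nd, MINUTES_PER_DAY)) < p_step)
    steps = np.zeros((nd, MINUTES_PER_DAY), dtype=np.int64)
    ns = int(stepping.sum())
    if ns:
        cad_mean = np.repeat(part["cadence_mean"].to_numpy(), d)
        cm = np.broadcast_to(cad_mean[:, None], (nd, MINUTES_PER_DAY))[stepping]
        # truncated normal with per-minute means via inverse-CDF draws
        a = (1.0 - cm) / am.cadence_sd
        b = (180.0 - cm) / am.cadence_sd
        u = rng.random(ns)
        from scipy.stats import norm
        cad = norm.ppf(norm.cdf(a) + u * (norm.cdf(b) - norm.cdf(a))) * am.cadence_sd + cm
        steps[stepping] = np.clip(np.rint(cad), 1, 180).astype(np.int64)

    # counts
    counts = np.zeros((nd, MINUTES_PER_DAY), dtype=np.int64)
    if ns:
        cps = rng.normal(am.counts_per_step_mean, am.counts_per_step_sd, size=ns)
        noise = rng.normal(0.0, am.counts_noise_sd, size=ns)
        c = np.rint(steps[stepping] * np.clip(cps, 1.0, None) + noise)
        # organic stepping minutes always carry plausible intensity; sub-500
        # stepping is injected via the explicit artifact channel below
        counts[stepping] = np.clip(c, 500, None).astype(np.int64)
    nonstep_wear = wear & ~stepping
    k = int(nonstep_wear.sum())
    if k:
        c = rng.poisson(am.nonstep_counts_mean, size=k)
        c[rng.random(k) < am.nonstep_zero_prob] = 0
        counts[nonstep_wear] = c

    clean_steps = steps.copy()
    clean_steps[counts < 500] = 0  # what an artifact-free QC pass would keep

    # artifacts (wear minutes only); spike takes precedence over low-count
    spike = wear & (rng.random((nd, MINUTES_PER_DAY)) < fm.p_spike_minute)
    lowc = wear & ~spike & (rng.random((nd, MINUTES_PER_DAY)) < fm.p_lowcount_step_minute)
    nsp = int(spike.sum())
    if nsp:
        s_lo, s_hi = fm.spike_cadence_range
        steps[spike] = rng.integers(s_lo, s_hi + 1, size=nsp)
        counts[spike] = rng.integers(500, 3000, size=nsp)  # intensity implausibly low for the cadence
    nlc = int(lowc.sum())
    if nlc:
        steps[lowc] = rng.integers(1, 41, size=nlc)
        counts[lowc] = rng.integers(0, 500, size=nlc)

    reliable = rng.random((nd, MINUTES_PER_DAY)) >= fm.p_unreliable_minute
    uncal = rng.random(config.n_participants) < fm.p_uncalibrated_participant
    calibrated = np.ones((nd, MINUTES_PER_DAY), dtype=bool)
    calibrated[np.repeat(uncal, d), :] = False

    return steps, counts, reliable, calibrated, clean_steps


def _latent_metrics(clean_steps: np.ndarray, n: int, d: int):
    """Latent peak30 and steps/day from the artifact-free censored matrix."""
    top30 = np.partition(clean_steps, MINUTES_PER_DAY - 30, axis=1)[:, -30:]
    peak30_day = top30.mean(axis=1).reshape(n, d)
    steps_day = clean_steps.sum(axis=1).reshape(n, d)
    return peak30_day.mean(axis=1), steps_day.mean(axis=1).astype(float)


def _draw_risk_states(config: GeneratorConfig, part: pd.DataFrame,
                      peak30_true: np.ndarray, rng: np.random.Generator):
    """Nested low/high Bernoulli risk states per factor with exact marginals.

    High state ~ Bernoulli(p_high(x)); the low state is a superset drawn
    conditionally so its marginal equals p_low(x) while low >= high always.
    """
    age = part["age"].to_numpy(dtype=float)
    smoking = part["smoking"].to_numpy(dtype=float)
    states, probs, intercepts = {}, {}, {}
    for fac in FACTORS:
        m_lo = config.risk_model[(fac, "low")]
        m_hi = config.risk_model[(fac, "high")]
        for sev, m in [("low", m_lo), ("high", m_hi)]:
            lp = m.beta_peak30 * peak30_true + m.beta_age * age + m.beta_smoking * smoking
            if m.intercept is not None:
                a = m.intercept
            else:
                a = solve_intercept(m.prevalence, lp)
            intercepts[(fac, sev)] = a
            probs[(fac, sev)] = expit(a + lp)
        p_lo, p_hi = probs[(fac, "low")], probs[(fac, "high")]
        if np.any(p_lo < p_hi - 1e-12):
            raise ConfigurationError(
                f"risk_model[{fac}]: low-severity risk must dominate high-severity risk"
            )
        hi = rng.random(len(part)) < p_hi
        # conditional draw keeps the low marginal exact while nesting high
        with np.errstate(divide="ignore", invalid="ignore"):
            p_cond = np.where(hi, 1.0, (p_lo - p_hi) / np.clip(1.0 - p_hi, 1e-12, None))
        lo = rng.random(len(part)) < p_cond
        states[(fac, "high")] = hi
        states[(fac, "low")] = lo | hi
    return states, probs, intercepts


def _draw_biomarkers(config: GeneratorConfig, part: pd.DataFrame,
                     states: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Biomarker values truncated to the region implied by each risk state,
    rounded to one decimal and nudged inside the region so derived labels
    always agree with the latent states."""
    n = len(part)
    out = {}
    sex = part["sex"].to_numpy()
    for fac, (direction, cuts, support) in _FACTOR_CUTS.items():
        vm = config.biomarker_model[fac]
        low_cut = np.where(sex == "male", cuts["male"][0], cuts["female"][0])
        high_cut = np.where(sex == "male", cuts["male"][1], cuts["female"][1])
        hi_state = states[(fac, "high")]
        lo_state = states[(fac, "low")]
        region = np.where(hi_state, 2, np.where(lo_state, 1, 0))
        vals = np.empty(n)
        s_lo, s_hi = support
        for r in (0, 1, 2):
            m = region == r
            if not m.any():
                continue
            if direction == "ge":
                bounds = {
                    0: (np.full(m.sum(), s_lo), low_cut[m] - 0.1),
                    1: (low_cut[m], high_cut[m] - 0.1),
                    2: (high_cut[m], np.full(m.sum(), s_hi)),
                }[r]
                mean = {
                    0: low_cut[m] - vm.offset,
                    1: (low_cut[m] + high_cut[m]) / 2.0,
                    2: high_cut[m] + vm.offset,
                }[r]
            else:  # 'le': at-risk is small values; low_cut > high_cut
                bounds = {
                    0: (low_cut[m] + 0.1, np.full(m.sum(), s_hi)),
                    1: (high_cut[m] + 0.1, low_cut[m]),
                    2: (np.full(m.sum(), s_lo), high_cut[m]),
                }[r]
                mean = {
                    0: low_cut[m] + vm.offset,
                    1: (low_cut[m] + high_cut[m]) / 2.0,
                    2: high_cut[m] - vm.offset,
                }[r]
            lo_b, hi_b = bounds
            a = (lo_b - mean) / vm.sd
            b = (hi_b - mean) / vm.sd
            from scipy.stats import norm
            u = rng.random(m.sum())
            v = norm.ppf(norm.cdf(a) + u * (norm.cdf(b) - norm.cdf(a))) * vm.sd + mean
            vals[m] = np.clip(np.round(v, 1), lo_b, hi_b)
        if vm.p_missing > 0:
            vals[rng.random(n) < vm.p_missing] = np.nan
        out[fac] = vals
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, d = config.n_participants, config.n_days

    part = _participant_frame(config, rng)
    steps, counts, reliable, calibrated, clean_steps = _generate_minutes(config, part, rng)
    peak30_true, steps_day_true = _latent_metrics(clean_steps, n, d)
    states, probs, intercepts = _draw_risk_states(config, part, peak30_true, rng)
    bio_vals = _draw_biomarkers(config, part, states, rng)

    nd = n * d
    minutes = pd.DataFrame(
        {
            "seqn": np.repeat(part["seqn"].to_numpy(), d * MINUTES_PER_DAY),
            "day": np.tile(np.repeat(np.arange(1, d + 1), MINUTES_PER_DAY), n),
            "minute": np.tile(np.arange(MINUTES_PER_DAY), nd),
            "counts": counts.reshape(-1),
            "steps": steps.reshape(-1),
            "paxstat": reliable.reshape(-1).astype(np.int64),
            "paxcal": calibrated.reshape(-1).astype(np.int64),
        }
    )

    biomarkers = pd.concat(
        [part[["seqn", "age", "sex", "smoking"]].reset_index(drop=True), bio_vals],
        axis=1,
    )
    biomarkers[["weight", "stratum", "psu"]] = part[["weight", "stratum", "psu"]].to_numpy()
    biomarkers = biomarkers[
        ["seqn", "age", "sex", "smoking", "bmi", "waist", "sbp", "dbp",
         "tg", "hdl", "glucose", "weight", "stratum", "psu"]
    ]

    # artifact bookkeeping mirroring the QC pipeline's stage definitions:
    # censorable/spike minutes are those the censor and cadence-ceiling
    # stages will act on among reliable, calibrated minutes
    ok = reliable & calibrated
    n_censorable = int(((steps > 0) & (counts < 500) & ok).sum())
    n_spikes = int(((steps > 180) & (counts >= 500) & ok).sum())

    truth_part = part.copy()
    truth_part["peak30_true"] = peak30_true
    truth_part["steps_day_true"] = steps_day_true
    for (fac, sev), st in states.items():
        truth_part[f"risk_{fac}_{sev}"] = st.astype(np.int64)
        truth_part[f"prob_{fac}_{sev}"] = probs[(fac, sev)]

    truth = {
        "config": config,
        "participants": truth_part,
        "intercepts": intercepts,
        "n_censorable_minutes": n_censorable,
        "n_spike_minutes": n_spikes,
    }
    return SyntheticCohort(minutes=minutes, biomarkers=biomarkers, truth=truth)


def default_nhanes_like_config(seed: int, n_participants: int = 2000,
                               n_days: int = 7) -> GeneratorConfig:
    """Fixed, documented configuration whose male stratum approximates the
    published national sample moments (steps/day ~6933, peak 30-min cadence
    ~70 steps/min).  The number of survey strata scales with cohort size so
    every PSU keeps enough members for between-PSU variance estimation even
    after complete-case subsetting."""
    n_strata = int(min(15, max(2, n_participants // 120)))
    return GeneratorConfig(n_participants=n_participants, n_days=n_days, seed=seed,
                           design_model=DesignModel(n_strata=n_strata))


# ---------------------------------------------------------------------------
# lightweight direct simulators for calibration / recovery experiments
# ---------------------------------------------------------------------------

def simulate_peak30_risk(n: int, rng: np.random.Generator, *,
                         alpha: float = None, beta: float = -0.03,
                         prevalence: float = 0.4,
                         peak30_mean: float = 68.0, peak30_sd: float = 21.5):
    """Draw (peak30, risk) pairs from a pure logistic link.

    peak30 ~ truncated normal on [5, 160] matching the published dispersion;
    risk ~ Bernoulli(expit(alpha + beta * peak30)).  If ``alpha`` is None it
    is solved so the expected prevalence equals ``prevalence``.  Returns
    (peak30, y, alpha, t_star) with t_star the population equal-J cutpoint.
    """
    x = _trunc_normal(rng, 5.0, 160.0, peak30_mean, peak30_sd, size=n)
    if alpha is None:
        ref = _trunc_normal(np.random.default_rng(987654321), 5.0, 160.0,
                            peak30_mean, peak30_sd, size=200_000)
        alpha = solve_intercept(prevalence, beta * ref)
        t_star = equal_j_cutpoint(alpha, beta, ref)
    else:
        ref = _trunc_normal(np.random.default_rng(987654321), 5.0, 160.0,
                            peak30_mean, peak30_sd, size=200_000)
        t_star = equal_j_cutpoint(alpha, beta, ref)
    y = (rng.random(n) < expit(alpha + beta * x)).astype(np.int64)
    return x, y, float(alpha), float(t_star)


def simulate_survey_logit(rng: np.random.Generator, *, n_strata: int = 12,
                          psus_per_stratum: int = 2, n_per_psu: int = 25,
                          beta: tuple = (-0.5, 0.8), cluster_x_sd: float = 0.5,
                          outcome_re_sd: float = 0.6, weight_sigma: float = 0.4):
    """Clustered logistic data for design-based variance experiments.

    The covariate has a PSU-level component and the linear predictor carries
    a PSU-level random intercept with SD ``outcome_re_sd``, so outcomes (and
    hence scores) are correlated within PSUs and naive iid variances are
    anticonservative.  The estimand of the design-based pseudo-ML fit is the
    *marginal* (census) logistic parameter, which the random intercept
    attenuates away from ``beta``; compute it with
    :func:`pseudo_true_logit_beta` under the same settings.  Returns a dict
    with y, X (with intercept), weights, stratum, psu and the conditional
    beta used.
    """
    n_psu = n_strata * psus_per_stratum
    n = n_psu * n_per_psu
    psu_eff = rng.normal(0.0, cluster_x_sd, size=n_psu)
    b_psu = rng.normal(0.0, outcome_re_sd, size=n_psu)
    stratum = np.repeat(np.arange(n_strata), psus_per_stratum * n_per_psu)
    psu = np.repeat(np.arange(n_psu), n_per_psu)
    x = psu_eff[psu] + rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    eta = X @ np.asarray(beta) + b_psu[psu]
    y = (rng.random(n) < expit(eta)).astype(np.int64)
    w = rng.lognormal(0.0, weight_sigma, size=n)
    w *= n / w.sum()
    return {"y": y, "X": X, "weights": w, "stratum": stratum, "psu": psu,
            "beta": np.asarray(beta, dtype=float)}


def pseudo_true_logit_beta(*, beta: tuple = (-0.5, 0.8), cluster_x_sd: float = 0.5,
                           outcome_re_sd: float = 0.6, n_population: int = 400_000,
                           seed: int = 123456789) -> np.ndarray:
    """Census (marginal) logistic parameter for the clustered simulator.

    Simulates one very large population from the same random-intercept model
    and fits an ordinary logistic regression to it; design-based CIs from
    :func:`simulate_survey_logit` samples should cover this vector.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    # many tiny 'clusters': equivalent to integrating the random effects
    b = rng.normal(0.0, outcome_re_sd, size=n_population)
    x = rng.normal(0.0, cluster_x_sd, size=n_population) + rng.normal(size=n_population)
    eta = beta[0] + beta[1] * x + b
    y = (rng.random(n_population) < expit(eta)).astype(float)
    X = np.column_stack([np.ones(n_population), x])
    # simple Newton iterations (no design needed for a census fit)
    coef = np.zeros(2)
    for _ in range(50):
        p = expit(X @ coef)
        W = np.clip(p * (1 - p), 1e-12, None)
        delta = np.linalg.solve((X.T * W) @ X, X.T @ (y - p))
        coef += delta
        if np.max(np.abs(delta)) < 1e-12:
            break
    return coef


def simulate_band_rule_data(n: int, rng: np.random.Generator, *,
                            noise_rate: float = 0.0):
    """Cadence-band feature rows with a planted 3-rule tree structure.

    True label (1 = at risk) follows the published tree shape: a person is
    risk-free (0) iff band7 > 0 AND band5 >= 4.2 AND band1 >= 9.8 minutes;
    otherwise at risk.  Labels are flipped independently with probability
    ``noise_rate`` (symmetric noise => Bayes accuracy 1 - noise_rate).
    Returns (X DataFrame with band0..band7, y_noisy, y_true).
    """
    cols = {}
    cols["band0"] = rng.gamma(20.0, 20.0, size=n)          # sedentary wear minutes
    cols["band1"] = rng.gamma(3.0, 8.0, size=n)            # straddles 9.8
    cols["band2"] = rng.gamma(2.0, 5.0, size=n)
    cols["band3"] = rng.gamma(1.5, 4.0, size=n)
    cols["band4"] = rng.gamma(1.2, 3.0, size=n)
    cols["band5"] = rng.gamma(1.5, 5.0, size=n)            # straddles 4.2
    cols["band6"] = rng.gamma(0.8, 2.0, size=n)
    band7 = rng.gamma(0.7, 3.0, size=n)
    band7[rng.random(n) < 0.40] = 0.0                      # many accumulate none
    cols["band7"] = band7
    X = pd.DataFrame({k: np.round(v, 2) for k, v in cols.items()})
    y_true = (~((X["band7"] > 0) & (X["band5"] >= 4.2) & (X["band1"] >= 9.8))).astype(np.int64)
    y = y_true.to_numpy().copy()
    if noise_rate > 0:
        flip = rng.random(n) < noise_rate
        y = np.where(flip, 1 - y, y)
    return X, y, y_true.to_numpy()
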