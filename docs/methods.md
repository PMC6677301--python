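# Methods

`cadencerisk` implements a complete analysis chain for deriving step-based
cardiometabolic risk thresholds from minute-epoch accelerometry, together
with a synthetic cohort generator that makes every stage testable against
known ground truth. This note records the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
experiments do and do not demonstrate.

## Accelerometer data treatment

Minute records carry activity counts (counts/min), step counts (steps/min)
and device quality flags (reliability, calibration). Cleaning applies, in
order:

1. **Adult restriction** — participants under 18 years are removed.
2. **Non-wear detection** — a minute is non-wear iff it lies inside a
   maximal run of ≥ 60 consecutive minutes with zero counts *and* zero
   steps. Runs are broken at day boundaries and clock gaps; they never
   span days. The rule is implemented declaratively (maximal zero runs)
   and verified against a brute-force run-enumeration oracle; a rolling-sum
   formulation is an implementation detail, the run rule is the contract.
3. **Quality flags** — minutes failing reliability or calibration are
   excluded from all downstream computation.
4. **Low-intensity step censor** — steps recorded at < 500 counts/min are
   set to zero (counts kept, wear status kept). Strict `<`: a 500-count
   minute survives. Sub-500-count stepping is implausible relative to
   pedometer-grade output and inflates steps/day.
5. **Cadence ceiling** — minutes over 180 steps/min have steps zeroed
   (strict `>`: 180 survives). Above that rate the device's step channel
   disagrees with its intensity channel. Only steps are zeroed, so wear
   time is unaffected; the source text says such data were "removed"
   without specifying wear-time impact, and keeping the minute's wear
   status is the conservative reading.
6. **Valid-day / valid-participant gates** — a valid day has ≥ 600 wear
   minutes (10 h); participants need ≥ 4 valid days.

Whether the censor runs before or after non-wear detection is immaterial
for the rules as stated (non-wear minutes have zero steps), but the
pipeline fixes the order above and is idempotent on its own output.

## Step metrics

Per valid day, over wear minutes:

* **steps/day** — total steps; the per-participant value is the unweighted
  mean over valid days (the field's convention when the aggregator is not
  otherwise specified).
* **peak 30-min cadence** — mean of the 30 highest (not necessarily
  consecutive) minute cadences; days with fewer than 30 wear minutes are
  zero-padded (such days are already invalid, so the choice only pins down
  edge-case determinism).
* **cadence bands** — wear minutes at 0 (zero cadence), 1–19 (incidental),
  20–39 (sporadic), 40–59 (purposeful), 60–79 (slow walking), 80–99
  (medium), 100–119 (brisk) and ≥ 120 steps/min (all faster ambulation).
  The eight bands partition the wear minutes exactly.
* **top-3 10-min bout steps** — greedy-by-value selection of three
  non-overlapping windows of 10 consecutive clock minutes: take the
  highest-sum window (ties to the earliest start), exclude overlaps,
  repeat. Greedy is the natural reading of "top 3 non-overlapping"; it is
  tested against an exhaustive enumeration of windows at each greedy step,
  and its gap to the globally optimal window triple (computed by dynamic
  programming) is quantified — they differ on only a few percent of random
  days, always with greedy ≤ optimal.

## Risk labels

Each factor is compared against paired low-risk / high-risk cutpoints with
the boundary included (BMI ≥ 25/30 kg/m²; waist M ≥ 94/102, F ≥ 80/88 cm;
SBP ≥ 120/130, DBP ≥ 80/85 mmHg; triglycerides ≥ 150/200 mg/dL;
HDL ≤ 59/40 mg/dL, the only ≤-direction factor; fasting glucose
≥ 100/126 mg/dL). "High blood pressure" is SBP and/or DBP over their
cutoffs, evaluated with Kleene logic so one observed, exceeding component
decides the label while an unobserved component leaves it missing
otherwise. Labels are tri-state (at risk / not / missing) so each analysis
keeps its maximal per-outcome sample.

Metabolic syndrome is at-risk status on ≥ 3 of 5 components and is missing
unless all five are determinable. The high-risk variant uses high-risk
waist, TG ≥ 150, sex-specific HDL (M ≤ 40 / F ≤ 50), BP ≥ 130 and/or
≥ 85, and glucose ≥ 100. A low-risk variant is defined by parallel
construction with the low-risk component cutpoints (low waist, TG ≥ 150,
HDL ≤ 59 both sexes, BP ≥ 120 and/or ≥ 80, glucose ≥ 100); the exact
component set behind a "low-risk metabolic syndrome" outcome is a genuine
open choice, and this parallel reading is the documented default.

## ROC thresholds

Lower activity predicts risk, so classification is *at risk iff the metric
falls below the threshold*. Candidate thresholds are midpoints between
consecutive distinct observed values plus ±∞ sentinels. The trapezoidal
AUC equals the case–control concordance P(case < control) + ½ P(tie)
exactly (verified to 1e-12 against an all-pairs oracle, ties included).
The reported threshold maximizes Youden's J = sensitivity + specificity − 1,
computed in exact integer arithmetic; ties break to higher specificity,
then lower threshold. AUC CIs use the DeLong structural-component
variance; threshold CIs use a stratified percentile bootstrap (cases and
controls resampled separately; B = 2000 by default, deterministic given a
seed). Age-stratified analyses use decade bins [18,29] … [70,85] × sex,
with degenerate strata (a missing class) reported, not fatal.

A calibration caveat worth stating plainly: the empirical Youden maximizer
is a cube-root-rate estimator. At n = 2000 with a logistic exposure–risk
link strong enough to give AUC ≈ 0.67 (the strongest discrimination seen
for these outcomes), its sampling SD is ≈ 4 steps/min, so individual
replicates land within ±5 steps/min of the population equal-J cutpoint
only ~80% of the time; the bootstrap *interval* nevertheless covers the
true cutpoint at ~95%. Point thresholds from cohorts of this size carry
several steps/min of uncertainty even when the interval is honest.

## Design-weighted logistic regression

Outcomes are regressed on one exposure (peak 30-min cadence or steps/day)
with optional age and smoking adjusters, by pseudo-maximum likelihood:
IRLS on the weighted Bernoulli log-likelihood (convergence when the max
coefficient step < 1e-10; perfect separation raises an error). The
covariance is the Taylor-linearization sandwich B⁻¹VB⁻¹, where B is the
weighted information and V the with-replacement between-PSU variance of
weighted score totals within strata, V = Σ_h n_h/(n_h−1) Σ_i (z_hi − z̄_h)
(z_hi − z̄_h)ᵀ. Strata with a single PSU are an error — no certainty-unit
fix-ups. Odds ratios are reported per 20 steps/min (one cadence band) or
per 1000 steps/day: OR = e^{sβ̂}, CI = e^{sβ̂ ± 1.96·s·SE(β̂)}. The OR is
reported with β̂'s fitted sign: values below 1 mean risk falls as activity
rises; the equivalent "times less likely per increase" phrasing is 1/OR.

Model ranking uses a pseudo-AIC, −2·(pseudo-log-likelihood with weights
rescaled to mean 1) + 2k. It is a ranking device at a fixed design, not a
design-adjusted information criterion, and is compared only across models
fitted to the identical row set. Logit-linearity is checked by empirical
logits in exposure-quantile bins (0.5 continuity correction) plus a
design-based Wald test of an added centred-quadratic term, flagged at
p < 0.05.

## Cadence-band decision tree

A from-scratch binary CART with Gini impurity. Splits search all features
and all midpoints between consecutive distinct values; a split is accepted
only when the *tree-total* impurity decrease reaches the complexity gate,
(n_node/n_root)·gain ≥ cp·impurity(root) — the recursive-partitioning
convention, which stops deep low-n splits from fitting label noise.
Defaults: min_split = 20, min_leaf = 7, cp = 0.01, max depth 30 — the
conventional recursive-partitioning defaults. Ties break to the lower
feature index then lower cutpoint (within 1e-12 of the best gain), so the
tree is deterministic and row-order invariant. Pre-pruning by the cp gate
replaces cost-complexity pruning with cross-validation: it is
deterministic and sufficient for the planted-rule experiments. No
surrogate splits; missing features are an error. Evaluation repeats
label-stratified 80/20 holdouts (1000 by default) and reports the mean
test accuracy.

## Synthetic cohort generator

The generator emulates the structure of a national accelerometer cohort;
every distributional choice is a stand-in (the emulated study describes no
generative model) calibrated once to published summary moments:

* **Wear**: wear 07:00–21:00 (840 min/day); 30% of days contain a 90-min
  midday non-wear run; 8% of days are skipped entirely. All minutes
  outside wear are zero-count, zero-step records.
* **Activity**: a shared per-participant latent drives both the
  probability that a wear minute is a stepping minute (base 0.16,
  between-person logit SD 0.55) and the participant's cadence level
  (mean 45, between SD 8 steps/min); stepping minutes draw cadence from a
  truncated normal on [1, 180] (within-person SD 15). Women step slightly
  less and slower. These values put the male stratum near the published
  moments (steps/day ≈ 6930, peak 30-min cadence ≈ 70 steps/min) after
  full QC.
* **Counts**: stepping minutes carry counts = steps × counts/step
  (≈ 30 ± 5) + noise, floored at 500 so that *organic* stepping minutes
  are never censorable — all sub-500-count stepping flows through the
  explicit artifact channel, which makes the QC bookkeeping oracles exact.
  Non-stepping wear minutes draw zero-inflated Poisson counts.
* **Artifacts**: low-count stepping minutes (counts < 500, steps 1–40) at
  rate 0.002, cadence spikes (181–250 steps/min, counts ≥ 500) at rate
  0.0005, unreliable minutes at 0.002, uncalibrated participants at 0.01.
  The truth record counts exactly the minutes each QC stage will act on.
* **Risk**: per factor and severity, a latent Bernoulli risk state with
  P(risk) = expit(α + β_peak30·peak30 + β_age·age + β_smoking·smoking),
  β_peak30 = −0.03 per steps/min, β_age = 0.02/yr, β_smoking = 0.3.
  peak30 here is the participant's artifact-free, censor-applied latent
  peak 30-min cadence, so pipeline recovery is tight. Intercepts are
  solved at generation time so expected prevalences hit per-factor targets
  exactly (recorded in the truth table); the low-severity state nests the
  high-severity state by a conditional draw that preserves both marginals.
* **Biomarkers**: values are drawn from normals truncated to the region
  the risk state implies (safe / low-only / high relative to the
  sex-specific cutpoints), rounded to one decimal and nudged inside the
  region — derived labels therefore agree with the latent states exactly.
  Missingness is per-variable (35% for the fasting labs, mirroring a
  fasting-subsample design; a few percent elsewhere), which reproduces the
  roughly one-third complete-metabolic-panel fraction seen in the emulated
  study.
* **Design**: participants are assigned to strata (scaling from 2 up to 15
  with cohort size) × 2 PSUs, balanced; weights are lognormal (σ = 0.5)
  normalized to sum to n.

What the generator does *not* model: oversampling, day-of-week and
seasonal structure, within-person autocorrelation of minutes beyond the
wear-run structure, biomarker measurement error unlinked to risk state,
and real covariance among biomarkers. Passing recovery tests therefore
demonstrates the correctness of the algorithms under a known data law, not
the field validity of the thresholds.

Separate lightweight simulators back the calibration experiments: a pure
logistic peak30–risk link (with the population equal-J cutpoint in closed
form via σ(α+βt*) = marginal prevalence), a clustered survey-logit
generator whose outcomes carry PSU-level random intercepts (coverage is
assessed against the census marginal parameter, computed by a 400k-row
reference fit, because that is the pseudo-MLE's estimand), and a
cadence-band generator with the planted three-rule tree (risk-free iff
band7 > 0 ∧ band5 ≥ 4.2 ∧ band1 ≥ 9.8 minutes; symmetric label noise at
rate r gives Bayes accuracy 1 − r).

## Problem sizes and seeds

All randomness flows from numpy `SeedSequence`: the pipeline's single seed
spawns per-stage child seeds (generation, ROC bootstraps, stratified ROC,
tree holdout), so stages are individually reproducible and two runs with
one seed are byte-identical. The test-suite experiments use cohorts of
150–2000 participants, 100–500 simulation replicates and bootstrap sizes
of 200–600, chosen so each experiment's Monte-Carlo error is small against
the property being checked; the acceptance script analyses a 1200-person,
7-day cohort with B = 1000 bootstraps and 500 holdout repetitions.

## Known limitations

* The low-risk metabolic-syndrome component set is a documented
  construction, not an externally fixed definition.
* Pseudo-AIC is not a design-based AIC; it is used only to rank models on
  a common row set.
* No replicate-weight (jackknife/BRR) variances, no multiple imputation,
  no partial AUC or cost-weighted cutpoints, no surrogate splits or
  cost-complexity pruning, no MET-based intensity categories.
* The SAS transport adapter maps the standard accelerometer variable
  layout only; it is untested against real survey files in this
  repository (no such files ship with it).
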