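# cadencerisk

Step-based cardiometabolic risk thresholds from minute-epoch accelerometry.

Hip-worn accelerometers that store step counts in one-minute epochs yield
two publicly interpretable physical-activity metrics: **steps/day**
(volume) and **peak 30-min cadence** (intensity — the mean of a day's 30
highest steps/min values, averaged over a week of valid wear). This
package implements, as a tested reusable pipeline, the derivation of
screening thresholds that relate these metrics to cardiometabolic risk
factors (BMI, waist circumference, blood pressure, triglycerides, HDL
cholesterol, fasting glucose, and 3-of-5 metabolic syndrome), for
epidemiologists and physical-activity researchers working with
NHANES-style cohorts.

The chain:

1. **QC** (`cadencerisk.qc`) — non-wear time as maximal runs of ≥ 60
   consecutive zero-count minutes; reliability/calibration flags; steps at
   < 500 counts/min censored; minutes > 180 steps/min removed; valid day
   = ≥ 10 h wear; valid participant = ≥ 4 valid days, age ≥ 18.
2. **Step metrics** (`cadencerisk.metrics`) — steps/day, peak 30-min
   cadence, minutes in eight cadence bands (0, 1–19, …, 100–119, ≥ 120
   steps/min), top-3 non-overlapping 10-min bout steps.
3. **Risk labels** (`cadencerisk.labels`) — tri-state (at risk / not /
   missing) labels per factor at paired low/high cutpoints, plus
   metabolic syndrome (≥ 3 of 5 components).
4. **ROC thresholds** (`cadencerisk.roc`) — at risk iff the metric falls
   below the threshold t; AUC (= concordance P(case < control) + ½ P(tie));
   the optimal t maximizes Youden's J = sensitivity + specificity − 1;
   DeLong CIs for the AUC, stratified percentile-bootstrap CIs for t;
   overall and by sex × age decade.
5. **Survey-weighted logistic regression** (`cadencerisk.svylogit`) —
   pseudo-ML with Taylor-linearized (between-PSU, within-stratum)
   variances; odds ratios per 20 steps/min or 1000 steps/day,
   OR = e^{sβ̂}, CI = e^{sβ̂ ± 1.96·s·SE(β̂)}; pseudo-AIC model ranking
   and a logit-linearity diagnostic.
6. **Cadence-band decision tree** (`cadencerisk.cart`) — from-scratch CART
   (Gini, exhaustive midpoint splits, rpart-style complexity gate) on
   band minutes, evaluated by 1000 stratified 80/20 holdouts.

A synthetic cohort generator (`cadencerisk.synthetic`) emulates the
minute-record and biomarker structure of a national accelerometer study
with known generative parameters — wear/non-wear runs, hurdle-model minute
cadences, low-count and > 180 steps/min artifacts, risk states drawn from
a logistic model on latent peak 30-min cadence, survey design — so that
every stage is testable for exact bookkeeping and parameter recovery.
See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
import cadencerisk as cr

cohort = cr.generate_cohort(cr.default_nhanes_like_config(seed=1, n_participants=400))
qc = cr.qc_pipeline(cohort.minutes, cohort.biomarkers)
pm = cr.participant_metrics(cr.daily_metrics(qc.clean_minutes))
labels = cr.label_all(cohort.biomarkers)
roc = cr.run_outcome_roc(pm, labels, ["mets_low"], metric_cols=("peak30",),
                         B=500, seed=2)
```

prints, via the fields of `qc.report`, `pm` and `roc.iloc[0]`:

```
retained: 394 of 400
spike minutes removed: 1043
mean steps/day: 6179   mean peak30: 62.5 steps/min
mets_low / peak30: AUC 0.66 [0.57, 0.74], threshold 58.7 [55.2, 70.0] steps/min
```

394 of 400 simulated participants survive the wear-time gates; the 1043
zeroed minutes equal the generator's injected > 180 steps/min spikes
exactly. A peak 30-min cadence below ≈ 59 steps/min classifies this
cohort's participants as at risk for low-threshold metabolic syndrome
with AUC 0.66 — the threshold's bootstrap CI spans ~15 steps/min at this
sample size, which is the honest precision of an empirical Youden
cutpoint. Continuing with the design-weighted model and the band tree:

```python
from cadencerisk.svylogit import LogitModelSpec, SurveyDesign, fit_weighted_logit

analysis = pm.merge(cohort.biomarkers, on="seqn").merge(labels, on="seqn")
design = SurveyDesign(analysis["weight"].to_numpy(),
                      analysis["stratum"].to_numpy(), analysis["psu"].to_numpy())
res = fit_weighted_logit(analysis, design,
                         LogitModelSpec("mets_low", "peak30", ("age", "smoking")))
print(res.odds_ratio("peak30", 20.0))
```

```
OR per +20 steps/min: 0.31 [0.11, 0.91]  (n=153)
holdout mean accuracy: 61.3%
```

i.e. raising peak 30-min cadence by one cadence band (20 steps/min) is
associated with roughly a two-thirds reduction in the odds of the
metabolic-syndrome label in this synthetic cohort (equivalently, ≈ 3.2
times less likely), adjusted for age and smoking, with survey-design
standard errors; the cadence-band tree classifies held-out participants
at 61% mean accuracy over 200 stratified 80/20 splits.

## Command line

```bash
cadencerisk all --seed 7 --out out/            # synthetic end-to-end run
cadencerisk simulate --seed 7 --out data/      # write minutes.csv + biomarkers.csv
cadencerisk qc --out data/ && cadencerisk metrics --out data/
```

`all` writes `step_metrics.csv`, `risk_labels.csv`, `roc_results.csv`,
`roc_stratified.csv`, `odds_ratios.csv`, `tree.json`/`tree.txt`,
`holdout.csv` and a `manifest.json` whose stage counts are monotone
through QC; two runs with the same seed are byte-identical. Files mode
(`mode: files` in a YAML config) runs the same pipeline on your own
minute/biomarker CSVs (schemas in `cadencerisk/io.py`).

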