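"""End-to-end orchestration: QC -> metrics -> labels -> ROC / logit / tree.

A single run is fully determined by its configuration and seed: the
top-level seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn`` (stage order: cohort generation,
ROC bootstraps, stratified ROC, tree holdout), so each stage is
individually reproducible.  All outputs are plain CSV/JSON; a run manifest
records the config hash, stage row counts and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as crio
from .cart import CARTConfig, CadenceBandTree, repeated_holdout, render_tree, tree_to_json
from .labels import ROC_OUTCOMES, RiskThresholdConfig, label_all, label_counts
from .metrics import BAND_NAMES, daily_metrics, participant_metrics
from .qc import QCConfig, qc_pipeline
from .roc import AgeSexStrata, run_outcome_roc, stratified_roc
from .svylogit import (ConvergenceError, LogitModelSpec, SurveyDesign,
                       fit_weighted_logit)
from .synthetic import GeneratorConfig, default_nhanes_like_config, generate_cohort

logger = logging.getLogger("cadencerisk")

__all__ = ["PipelineConfig", "RunManifest", "run_full_pipeline", "PipelineError"]

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    mode: str = "synthetic"              # 'synthetic' | 'files'
    minute_csv: str | None = None        # files mode inputs
    biomarker_csv: str | None = None
    out_dir: str = "out"
    seed: int = 0
    n_participants: int = 300            # synthetic mode size
    n_days: int = 7
    qc: QCConfig = field(default_factory=QCConfig)
    roc_bootstrap: int = 2000
    stratified_roc_bootstrap: int = 500
    logit_outcomes: tuple = ("mets_low", "mets_high", "waist_low", "waist_high",
                             "high_bp_low", "high_bp_high")
    cart: CARTConfig = field(default_factory=CARTConfig)
    cart_outcome: str = "mets_low"
    holdout_reps: int = 1000

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files":
            for p, name in [(self.minute_csv, "minute_csv"),
                            (self.biomarker_csv, "biomarker_csv")]:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QCConfig(**raw.pop("qc", {}))
        cart = CARTConfig(**raw.pop("cart", {}))
        for key in ("logit_outcomes",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(qc=qc, cart=cart, **raw)

    def to_canonical_yaml(self) -> str:
        d = asdict(self)
        d["logit_outcomes"] = list(self.logit_outcomes)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        # where outputs land does not change what is computed
        d = asdict(self)
        d.pop("out_dir")
        d["logit_outcomes"] = list(self.logit_outcomes)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_seeds: dict
    counts: dict                         # monotone through QC stages
    timings: dict

    def to_json(self) -> str:
        # timings are excluded: manifest bytes must be identical across
        # repeat runs with the same seed
        d = asdict(self)
        d.pop("timings")
        return json.dumps(d, sort_keys=True, indent=1)


def _stage(name, log):
    t0 = time.perf_counter()

    def done():
        dt = time.perf_counter() - t0
        log[name] = round(dt, 3)
        logger.info("stage %-10s %.2fs", name, dt)

    return done


def run_full_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, writing every output table under ``out_dir``.

    Deterministic given the seed; partially written outputs are removed if
    a stage fails.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict = {}

    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(4)
    stage_seeds = {
        "generate": int(child[0].generate_state(1)[0]),
        "roc": int(child[1].generate_state(1)[0]),
        "stratified_roc": int(child[2].generate_state(1)[0]),
        "holdout": int(child[3].generate_state(1)[0]),
    }

    def emit(df_or_text, name: str):
        p = out / name
        if isinstance(df_or_text, pd.DataFrame):
            df_or_text.to_csv(p, index=False)
        else:
            p.write_text(df_or_text)
        written.append(p)
        return p

    counts: dict = {}
    try:
        # ---- input stage ------------------------------------------------
        done = _stage("input", timings)
        if config.mode == "synthetic":
            gc = default_nhanes_like_config(stage_seeds["generate"],
                                            n_participants=config.n_participants,
                                            n_days=config.n_days)
            cohort = generate_cohort(gc)
            minutes, biomarkers = cohort.minutes, cohort.biomarkers
            emit(minutes, "minutes.csv")
            crio.write_biomarker_csv(biomarkers, out / "biomarkers.csv")
            written.append(out / "biomarkers.csv")
        else:
            minutes = crio.read_minute_csv(config.minute_csv)
            biomarkers = crio.read_biomarker_csv(config.biomarker_csv)
        counts["participants_in"] = int(minutes["seqn"].nunique())
        counts["minutes_in"] = int(len(minutes))
        done()

        # ---- QC ----------------------------------------------------------
        done = _stage("qc", timings)
        try:
            qres = qc_pipeline(minutes, biomarkers, config.qc)
        except Exception as e:
            raise PipelineError(f"qc: {e}") from e
        counts["participants_valid_accel"] = qres.report.participants_retained
        counts["qc_report"] = qres.report.as_dict()
        emit(pd.DataFrame([qres.report.as_dict()]).drop(
            columns=["participants_missing_biomarkers"]), "qc_report.csv")
        done()

        # ---- metrics -----------------------------------------------------
        done = _stage("metrics", timings)
        try:
            daily = daily_metrics(qres.clean_minutes)
            pmetrics = participant_metrics(daily, config.qc.min_valid_days)
        except Exception as e:
            raise PipelineError(f"metrics: {e}") from e
        counts["participants_with_metrics"] = int(len(pmetrics))
        emit(pmetrics, "step_metrics.csv")
        done()

        # ---- labels ------------------------------------------------------
        done = _stage("labels", timings)
        try:
            bio_kept = biomarkers[biomarkers["seqn"].isin(pmetrics["seqn"])]
            labels = label_all(bio_kept, RiskThresholdConfig())
            lcounts = label_counts(labels)
        except Exception as e:
            raise PipelineError(f"labels: {e}") from e
        counts["label_counts"] = {
            r["outcome"]: {"cases": r["cases"], "controls": r["controls"],
                           "missing": r["missing"]}
            for r in lcounts.to_dict("records")
        }
        counts["participants_complete_mets_panel"] = int(
            labels["mets_high"].notna().sum())
        emit(labels.astype(object).where(labels.notna(), ""), "risk_labels.csv")
        emit(lcounts, "label_counts.csv")
        done()

        # ---- ROC ---------------------------------------------------------
        done = _stage("roc", timings)
        outcome_cols = [f"{o}_{s}" for o in ROC_OUTCOMES for s in ("low", "high")]
        try:
            roc_tab = run_outcome_roc(pmetrics, labels, outcome_cols,
                                      B=config.roc_bootstrap,
                                      seed=stage_seeds["roc"])
            strat_tab = stratified_roc(pmetrics, labels, biomarkers,
                                       strata=AgeSexStrata(),
                                       B=config.stratified_roc_bootstrap,
                                       seed=stage_seeds["stratified_roc"])
        except Exception as e:
            raise PipelineError(f"roc: {e}") from e
        emit(roc_tab, "roc_results.csv")
        emit(strat_tab, "roc_stratified.csv")
        done()

        # ---- survey logit ------------------------------------------------
        done = _stage("logit", timings)
        try:
            analysis = pmetrics.merge(biomarkers, on="seqn").merge(labels, on="seqn")
            design = SurveyDesign(analysis["weight"].to_numpy(),
                                  analysis["stratum"].to_numpy(),
                                  analysis["psu"].to_numpy())
            or_rows = []
            for outcome in config.logit_outcomes:
                for exposure in ("peak30", "steps_per_day"):
                    spec = LogitModelSpec(outcome=outcome, exposure=exposure,
                                          adjusters=("age", "smoking"))
                    try:
                        res = fit_weighted_logit(analysis, design, spec)
                    except (ConvergenceError, ValueError) as e:
                        logger.warning("logit %s/%s skipped: %s", outcome, exposure, e)
                        continue
                    orr = res.odds_ratio(exposure, spec.scale)
                    or_rows.append({
                        "outcome": outcome, "exposure": exposure,
                        "scale": spec.scale, "or": orr.odds_ratio,
                        "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                        "beta": float(res.params[1]),
                        "se": float(res.bse[1]),
                        "pseudo_aic": res.aic, "n": res.nobs,
                    })
            or_tab = pd.DataFrame(or_rows)
        except Exception as e:
            raise PipelineError(f"logit: {e}") from e
        emit(or_tab, "odds_ratios.csv")
        done()

        # ---- cadence-band tree ---------------------------------------------
        done = _stage("tree", timings)
        try:
            band_cols = list(BAND_NAMES)
            tdata = pmetrics.merge(labels[["seqn", config.cart_outcome]], on="seqn")
            tdata = tdata[tdata[config.cart_outcome].notna()]
            Xb = tdata[band_cols]
            yb = tdata[config.cart_outcome].astype(bool).to_numpy().astype(np.int64)
            est = CadenceBandTree(config.cart).fit(Xb, yb)
            hold = repeated_holdout(Xb, yb, config.cart,
                                    n_reps=config.holdout_reps,
                                    seed=stage_seeds["holdout"])
        except Exception as e:
            raise PipelineError(f"tree: {e}") from e
        emit(tree_to_json(est.tree_), "tree.json")
        emit(render_tree(est.tree_, band_cols) + "\n", "tree.txt")
        emit(pd.DataFrame({"rep": np.arange(1, hold.n_reps + 1),
                           "accuracy": hold.accuracies}), "holdout.csv")
        counts["tree_n"] = int(len(yb))
        counts["holdout_mean_accuracy"] = round(hold.mean_accuracy, 6)
        done()

        manifest = RunManifest(
            config_hash=config.config_hash(),
            version=__version__,
            seed=config.seed,
            stage_seeds=stage_seeds,
            counts=counts,
            timings=timings,
        )
        (out / "manifest.json").write_text(manifest.to_json())
        written.append(out / "manifest.json")
        return manifest
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
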