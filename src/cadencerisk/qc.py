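"""Accelerometer data-treatment (QC) rules for minute-epoch records.

The cleaning contract, applied in order:

1. restrict to adults (age >= 18, from the biomarker table);
2. flag non-wear time: any minute inside a maximal run of >= 60 consecutive
   zero-count, zero-step minutes (runs never span day boundaries);
3. keep only minutes flagged reliable (PAXSTAT) and calibrated (PAXCAL);
4. censor steps recorded at intensities below 500 activity counts/min
   (steps set to 0, counts kept — sub-500-count stepping is implausible
   relative to pedometer output);
5. zero any minute over 180 steps/min (cadence/intensity disagreement above
   that rate indicates device error); the minute keeps its wear status;
6. a valid day has >= 600 wear minutes (10 h); participants need >= 4 valid
   days to be retained.

Boundary semantics are strict: counts of exactly 500 and cadences of
exactly 180 steps/min survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "QCReport",
    "QCResult",
    "flag_reliability",
    "detect_nonwear",
    "censor_low_intensity_steps",
    "remove_implausible_cadence",
    "valid_days",
    "filter_participants",
    "qc_pipeline",
]


class OrderingError(ValueError):
    """Raised when minute records are not sorted by (participant, day, minute)."""


@dataclass
class QCConfig:
    nonwear_run_minutes: int = 60
    valid_day_wear_minutes: int = 600   # 10 h
    min_valid_days: int = 4
    count_censor_floor: int = 500       # counts/min; strict '<' censors
    cadence_ceiling: int = 180          # steps/min; strict '>' removes
    min_age_years: int = 18

    def __post_init__(self):
        for name in ("nonwear_run_minutes", "valid_day_wear_minutes",
                     "min_valid_days", "count_censor_floor",
                     "cadence_ceiling", "min_age_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"QCConfig.{name} must be positive")


@dataclass
class QCReport:
    """Per-stage removal bookkeeping."""

    n_minutes_in: int = 0
    n_participants_in: int = 0
    nonwear_minutes: int = 0
    unreliable_minutes: int = 0
    censored_minutes: int = 0
    spike_minutes: int = 0
    invalid_days: int = 0
    participants_removed_age: int = 0
    participants_removed_days: int = 0
    participants_retained: int = 0
    participants_missing_biomarkers: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["participants_missing_biomarkers"] = list(self.participants_missing_biomarkers)
        return d


@dataclass
class QCResult:
    clean_minutes: pd.DataFrame   # wear minutes of valid days, retained participants
    report: QCReport
    valid_day_index: pd.DataFrame  # seqn, day for every valid day of retained participants


def _check_sorted(records: pd.DataFrame) -> None:
    key = (records["seqn"].astype(np.int64) * 10_000 + records["day"].astype(np.int64)
           ) * 10_000 + records["minute"].astype(np.int64)
    if not key.is_monotonic_increasing:
        raise OrderingError("minute records must be sorted by (seqn, day, minute)")


def flag_reliability(records: pd.DataFrame) -> pd.Series:
    """True where the minute is both reliable (paxstat) and calibrated (paxcal)."""
    _check_sorted(records)
    return (records["paxstat"].astype(bool) & records["paxcal"].astype(bool)).rename("reliable")


def detect_nonwear(records: pd.DataFrame, config: QCConfig | None = None) -> pd.Series:
    """Non-wear mask: minutes inside maximal zero runs >= the run threshold.

    A 'zero' minute has both counts == 0 and steps == 0.  Runs are broken by
    participant/day changes and by clock gaps, so non-wear never spans days.
    """
    config = config or QCConfig()
    _check_sorted(records)
    counts = records["counts"].to_numpy()
    steps = records["steps"].to_numpy()
    zero = (counts == 0) & (steps == 0)

    seqn = records["seqn"].to_numpy()
    day = records["day"].to_numpy()
    minute = records["minute"].to_numpy()
    n = len(records)
    if n == 0:
        return pd.Series(np.zeros(0, dtype=bool), index=records.index, name="nonwear")

    new_block = np.ones(n, dtype=bool)
    new_block[1:] = (
        (seqn[1:] != seqn[:-1])
        | (day[1:] != day[:-1])
        | (minute[1:] != minute[:-1] + 1)
        | (zero[1:] != zero[:-1])
    )
    run_id = np.cumsum(new_block) - 1
    run_len = np.bincount(run_id)
    nonwear = zero & (run_len[run_id] >= config.nonwear_run_minutes)
    return pd.Series(nonwear, index=records.index, name="nonwear")


def censor_low_intensity_steps(records: pd.DataFrame,
                               config: QCConfig | None = None):
    """Zero steps where counts fall below the censor floor (strict '<').

    Counts are unchanged and the minute keeps its wear status.  Returns
    (new records, number of minutes whose steps were zeroed).
    """
    config = config or QCConfig()
    out = records.copy()
    hit = (out["counts"] < config.count_censor_floor) & (out["steps"] > 0)
    out.loc[hit, "steps"] = 0
    return out, int(hit.sum())


def remove_implausible_cadence(records: pd.DataFrame,
                               config: QCConfig | None = None):
    """Zero steps for minutes over the cadence ceiling (strict '>').

    Counts are kept, so wear time is unaffected.  Returns (new records,
    number of spike minutes zeroed).
    """
    config = config or QCConfig()
    out = records.copy()
    hit = out["steps"] > config.cadence_ceiling
    out.loc[hit, "steps"] = 0
    return out, int(hit.sum())


def valid_days(records: pd.DataFrame, wear: pd.Series,
               config: QCConfig | None = None) -> pd.DataFrame:
    """Per (seqn, day) wear-minute totals and validity (>= 600 wear minutes)."""
    config = config or QCConfig()
    g = (
        pd.DataFrame({"seqn": records["seqn"], "day": records["day"],
                      "wear": wear.to_numpy()})
        .groupby(["seqn", "day"], sort=True)["wear"].sum().rename("wear_minutes")
        .reset_index()
    )
    g["valid"] = g["wear_minutes"] >= config.valid_day_wear_minutes
    return g


def filter_participants(day_table: pd.DataFrame, biomarkers: pd.DataFrame | None,
                        config: QCConfig | None = None):
    """Apply the valid-day gate and the adult age restriction.

    Returns (retained seqn array, removed_age, removed_days, missing_bio list).
    Participants present in minute records but absent from the biomarker
    table are retained (their age cannot be checked) and listed.
    """
    config = config or QCConfig()
    per = day_table.groupby("seqn")["valid"].sum()
    enough_days = per[per >= config.min_valid_days].index.to_numpy()
    removed_days = int((per < config.min_valid_days).sum())

    missing_bio: list = []
    removed_age = 0
    if biomarkers is not None:
        ages = biomarkers.set_index("seqn")["age"]
        all_ids = per.index.to_numpy()
        missing_bio = [int(s) for s in all_ids if s not in ages.index]
        known = ages.reindex(enough_days)
        too_young = known.index[(known.notna()) & (known < config.min_age_years)]
        removed_age = int(len(too_young))
        retained = np.setdiff1d(enough_days, too_young.to_numpy())
    else:
        retained = enough_days
    return retained, removed_age, removed_days, missing_bio


def qc_pipeline(minutes: pd.DataFrame, biomarkers: pd.DataFrame | None = None,
                config: QCConfig | None = None) -> QCResult:
    """Full data-treatment pipeline; idempotent on its own output.

    Order: adult restriction -> non-wear detection -> reliability/calibration
    -> low-intensity step censor -> cadence-ceiling removal -> valid-day and
    valid-participant gates.  Stage counts are reported for minutes still in
    play when each stage runs.
    """
    config = config or QCConfig()
    report = QCReport(
        n_minutes_in=len(minutes),
        n_participants_in=int(minutes["seqn"].nunique()),
    )
    records = minutes.sort_values(["seqn", "day", "minute"], kind="mergesort").reset_index(drop=True)

    # age restriction first: drop known minors entirely
    if biomarkers is not None:
        ages = biomarkers.set_index("seqn")["age"]
        minor_ids = set(ages.index[ages < config.min_age_years])
        if minor_ids:
            report.participants_removed_age = len(
                minor_ids & set(records["seqn"].unique())
            )
            records = records[~records["seqn"].isin(minor_ids)].reset_index(drop=True)

    nonwear = detect_nonwear(records, config)
    report.nonwear_minutes = int(nonwear.sum())

    reliable = flag_reliability(records)
    report.unreliable_minutes = int((~reliable & ~nonwear).sum())

    in_play = ~nonwear & reliable
    wear_frame = records[in_play].reset_index(drop=True)

    wear_frame, n_cens = censor_low_intensity_steps(wear_frame, config)
    report.censored_minutes = n_cens
    wear_frame, n_spike = remove_implausible_cadence(wear_frame, config)
    report.spike_minutes = n_spike

    # wear minutes = not non-wear and passing reliability
    day_table = valid_days(records, in_play, config)
    report.invalid_days = int((~day_table["valid"]).sum())

    retained, rm_age2, rm_days, missing_bio = filter_participants(
        day_table, biomarkers, config
    )
    report.participants_removed_days = rm_days
    report.participants_removed_age += rm_age2
    report.participants_missing_biomarkers = missing_bio
    report.participants_retained = int(len(retained))

    valid_idx = day_table.loc[
        day_table["valid"] & day_table["seqn"].isin(retained), ["seqn", "day"]
    ].reset_index(drop=True)

    clean = wear_frame.merge(valid_idx, on=["seqn", "day"], how="inner")
    clean = clean.sort_values(["seqn", "day", "minute"], kind="mergesort").reset_index(drop=True)
    return QCResult(clean_minutes=clean, report=report, valid_day_index=valid_idx)
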