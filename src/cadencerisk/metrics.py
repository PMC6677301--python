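"""Step-based physical-activity metrics from cleaned minute records.

Metrics per valid wear day, then averaged (unweighted) across a
participant's valid days:

* steps/day — total steps over wear minutes;
* peak 30-min cadence — mean of the 30 highest (not necessarily
  consecutive) minute cadences of the day; days with fewer than 30 wear
  minutes are zero-padded before averaging;
* cadence-band minutes — wear minutes spent at 0, 1-19, 20-39, 40-59,
  60-79, 80-99, 100-119 and >= 120 steps/min (zero cadence, incidental,
  sporadic, purposeful, slow / medium / brisk walking, faster ambulation);
* top-3 10-min bout steps — greedy selection of the 3 highest-step
  non-overlapping windows of 10 consecutive clock minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qc import QCResult

__all__ = [
    "BAND_EDGES",
    "BAND_NAMES",
    "daily_steps",
    "peak30_for_day",
    "cadence_band_minutes",
    "top3_bout10_steps",
    "daily_metrics",
    "participant_metrics",
    "compute_step_metrics",
]

# half-open upper edges for bands 1..6; band 0 is exactly zero, band 7 open-ended
BAND_EDGES = (1, 20, 40, 60, 80, 100, 120)
BAND_NAMES = tuple(f"band{i}" for i in range(8))

MINUTES_PER_DAY = 1440
_BOUT_LEN = 10


def daily_steps(wear_steps: np.ndarray) -> int:
    """Total steps over the day's wear minutes."""
    return int(np.asarray(wear_steps).sum())


def peak30_for_day(wear_steps: np.ndarray) -> float:
    """Mean of the 30 largest minute-step values; zero-padded under 30 minutes."""
    v = np.asarray(wear_steps, dtype=float)
    if v.size == 0:
        raise ValueError("day has no wear minutes; exclude upstream")
    if v.size < 30:
        v = np.concatenate([v, np.zeros(30 - v.size)])
    top = np.partition(v, v.size - 30)[-30:]
    return float(top.mean())


def cadence_band_minutes(wear_steps: np.ndarray) -> np.ndarray:
    """Minutes in each of the 8 cadence bands; partitions the wear minutes."""
    v = np.asarray(wear_steps)
    edges = np.array((0,) + BAND_EDGES + (np.inf,))
    # band 0 is exactly 0 steps; np.histogram's rightmost closed edge is
    # irrelevant here because the last band is open-ended
    out = np.empty(8, dtype=np.int64)
    out[0] = int((v == 0).sum())
    for i in range(1, 8):
        out[i] = int(((v >= edges[i]) & (v < edges[i + 1])).sum())
    return out


def top3_bout10_steps(steps_by_clock_minute: np.ndarray, n_bouts: int = 3) -> int:
    """Greedy top-k non-overlapping 10-minute bout steps.

    ``steps_by_clock_minute`` is a full-day array (non-wear minutes as 0).
    Windows are 10 consecutive clock minutes; the highest-sum window is
    taken first (ties to the earliest start), overlapping windows are then
    excluded, and the selection repeats up to ``n_bouts`` times.
    """
    v = np.asarray(steps_by_clock_minute, dtype=np.int64)
    if v.size < _BOUT_LEN:
        return int(v.sum())
    cs = np.concatenate([[0], np.cumsum(v)])
    win = cs[_BOUT_LEN:] - cs[:-_BOUT_LEN]          # window sums by start minute
    win = win.astype(float)
    total = 0
    for _ in range(n_bouts):
        j = int(np.argmax(win))                     # ties -> earliest start
        if not np.isfinite(win[j]):
            break
        total += int(win[j])
        lo = max(0, j - (_BOUT_LEN - 1))
        win[lo:j + _BOUT_LEN] = -np.inf             # exclude overlaps
        if np.all(np.isneginf(win)):
            break
    return total


def daily_metrics(clean_minutes: pd.DataFrame) -> pd.DataFrame:
    """Per (seqn, day) metrics from cleaned (wear-only) minute records."""
    if clean_minutes.empty:
        cols = ["seqn", "day", "wear_minutes", "steps_total", "peak30_day",
                *BAND_NAMES, "bout10_top3"]
        return pd.DataFrame(columns=cols)

    df = clean_minutes.sort_values(["seqn", "day", "minute"], kind="mergesort")
    combo = df["seqn"].to_numpy(np.int64) * 100_000 + df["day"].to_numpy(np.int64)
    day_key, uniq = pd.factorize(combo, sort=True)
    n_days = len(uniq)
    seqn_of_day = uniq // 100_000
    day_of_day = uniq % 100_000

    dense = np.zeros((n_days, MINUTES_PER_DAY), dtype=np.int64)
    wear = np.zeros((n_days, MINUTES_PER_DAY), dtype=bool)
    mins = df["minute"].to_numpy()
    dense[day_key, mins] = df["steps"].to_numpy()
    wear[day_key, mins] = True

    wear_minutes = wear.sum(axis=1)
    steps_total = dense.sum(axis=1)

    # top-30 of the dense row equals zero-padded wear values: non-wear
    # entries are 0 and step counts are non-negative
    top30 = np.partition(dense, MINUTES_PER_DAY - 30, axis=1)[:, -30:]
    peak30_day = top30.mean(axis=1)

    edges = np.array((0,) + BAND_EDGES + (np.inf,))
    bands = np.zeros((n_days, 8), dtype=np.int64)
    bands[:, 0] = ((dense == 0) & wear).sum(axis=1)
    for i in range(1, 8):
        bands[:, i] = ((dense >= edges[i]) & (dense < edges[i + 1]) & wear).sum(axis=1)

    bouts = np.fromiter(
        (top3_bout10_steps(dense[i]) for i in range(n_days)),
        dtype=np.int64, count=n_days,
    )

    out = pd.DataFrame(
        {
            "seqn": seqn_of_day,
            "day": day_of_day,
            "wear_minutes": wear_minutes,
            "steps_total": steps_total,
            "peak30_day": peak30_day,
            "bout10_top3": bouts,
        }
    )
    for i, name in enumerate(BAND_NAMES):
        out[name] = bands[:, i]
    return out[["seqn", "day", "wear_minutes", "steps_total", "peak30_day",
                *BAND_NAMES, "bout10_top3"]]


def participant_metrics(daily: pd.DataFrame, min_valid_days: int = 4) -> pd.DataFrame:
    """Unweighted means across valid days per participant.

    ``daily`` must already contain only valid days.  Participants with
    fewer than ``min_valid_days`` rows are dropped.
    """
    if daily.empty:
        raise ValueError("no daily metrics to aggregate")
    agg_cols = ["steps_total", "peak30_day", *BAND_NAMES, "bout10_top3"]
    g = daily.groupby("seqn", sort=True)
    n_days = g.size().rename("n_valid_days")
    means = g[agg_cols].mean()
    out = pd.concat([n_days, means], axis=1).reset_index()
    out = out[out["n_valid_days"] >= min_valid_days].reset_index(drop=True)
    out = out.rename(columns={"steps_total": "steps_per_day",
                              "peak30_day": "peak30",
                              "bout10_top3": "bout10_top3_mean"})
    return out


def compute_step_metrics(qc_result: QCResult, min_valid_days: int = 4) -> pd.DataFrame:
    """QC output -> per-participant step metrics table."""
    daily = daily_metrics(qc_result.clean_minutes)
    return participant_metrics(daily, min_valid_days=min_valid_days)
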