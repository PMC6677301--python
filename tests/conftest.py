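import numpy as np
import pandas as pd
import pytest

from cadencerisk import (GeneratorConfig, default_nhanes_like_config,
                         generate_cohort, label_all, qc_pipeline,
                         daily_metrics, participant_metrics)


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort reused across modules (one generation per session)."""
    return generate_cohort(default_nhanes_like_config(20250924, n_participants=150,
                                                      n_days=7))


@pytest.fixture(scope="session")
def small_qc(small_cohort):
    return qc_pipeline(small_cohort.minutes, small_cohort.biomarkers)


@pytest.fixture(scope="session")
def small_daily(small_qc):
    return daily_metrics(small_qc.clean_minutes)


@pytest.fixture(scope="session")
def small_metrics(small_daily):
    return participant_metrics(small_daily)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return label_all(small_cohort.biomarkers)


def make_day(zeros_runs, fill_counts=1000, fill_steps=20, seqn=1, day=1):
    """One full 1440-minute day; ``zeros_runs`` = list of (start, length)
    all-zero stretches, every other minute active."""
    counts = np.full(1440, fill_counts, dtype=np.int64)
    steps = np.full(1440, fill_steps, dtype=np.int64)
    for start, length in zeros_runs:
        counts[start:start + length] = 0
        steps[start:start + length] = 0
    return pd.DataFrame({
        "seqn": seqn, "day": day, "minute": np.arange(1440),
        "counts": counts, "steps": steps, "paxstat": 1, "paxcal": 1,
    })
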