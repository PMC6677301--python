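"""Binary cardiometabolic risk labels from biomarker records.

Each factor has paired low-risk and high-risk cutpoints (the low-risk
cutoff is always at least as lenient as the high-risk one in the risk
direction), compared with the boundary included:

====================  =======================  =======================
factor                low-risk (at risk if)    high-risk (at risk if)
====================  =======================  =======================
BMI                   >= 25 kg/m^2             >= 30 kg/m^2
waist (M / F)         >= 94 / >= 80 cm         >= 102 / >= 88 cm
SBP                   >= 120 mmHg              >= 130 mmHg
DBP                   >= 80 mmHg               >= 85 mmHg
high blood pressure   SBP >= 120 or DBP >= 80  SBP >= 130 or DBP >= 85
fasting glucose       >= 100 mg/dL             >= 126 mg/dL
HDL cholesterol       <= 59 mg/dL              <= 40 mg/dL
triglycerides         >= 150 mg/dL             >= 200 mg/dL
====================  =======================  =======================

Metabolic syndrome is at-risk status on >= 3 of 5 components.  The
high-risk variant uses high-risk waist, TG >= 150, sex-specific HDL
(M <= 40 / F <= 50), blood pressure >= 130 and/or >= 85, and glucose
>= 100.  The low-risk variant applies the same 3-of-5 rule to the
low-risk component cutpoints (low waist; TG >= 150; HDL <= 59 for both
sexes; BP >= 120 and/or >= 80; glucose >= 100).

Labels are tri-state (at risk / not at risk / missing) so that each
downstream analysis can use the maximal per-outcome sample; a metabolic
syndrome label is missing unless all five components are determinable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RiskThresholdConfig",
    "FACTOR_OUTCOMES",
    "ROC_OUTCOMES",
    "ALL_LABEL_COLUMNS",
    "label_factor",
    "label_high_blood_pressure",
    "label_mets",
    "label_all",
    "label_counts",
]

FACTOR_OUTCOMES = ("bmi", "waist", "sbp", "dbp", "tg", "hdl", "glucose")
# outcomes analysed per severity in the ROC / OR tables
ROC_OUTCOMES = ("mets", "high_bp", "waist", "tg", "hdl", "glucose", "bmi")
SEVERITIES = ("low", "high")
ALL_LABEL_COLUMNS = tuple(
    f"{o}_{s}" for o in (*FACTOR_OUTCOMES, "high_bp", "mets") for s in SEVERITIES
)


def _default_cuts() -> dict:
    # factor -> (direction, {severity: {sex: cut}})
    both = lambda v: {"male": v, "female": v}
    return {
        "bmi": ("ge", {"low": both(25.0), "high": both(30.0)}),
        "waist": ("ge", {"low": {"male": 94.0, "female": 80.0},
                         "high": {"male": 102.0, "female": 88.0}}),
        "sbp": ("ge", {"low": both(120.0), "high": both(130.0)}),
        "dbp": ("ge", {"low": both(80.0), "high": both(85.0)}),
        "tg": ("ge", {"low": both(150.0), "high": both(200.0)}),
        "hdl": ("le", {"low": both(59.0), "high": both(40.0)}),
        "glucose": ("ge", {"low": both(100.0), "high": both(126.0)}),
    }


def _default_mets() -> dict:
    both = lambda v: {"male": v, "female": v}
    return {
        "k": 3,
        "high": {
            "waist": ("ge", {"male": 102.0, "female": 88.0}),
            "tg": ("ge", both(150.0)),
            "hdl": ("le", {"male": 40.0, "female": 50.0}),
            "bp": ("orge", {"sbp": 130.0, "dbp": 85.0}),
            "glucose": ("ge", both(100.0)),
        },
        "low": {
            "waist": ("ge", {"male": 94.0, "female": 80.0}),
            "tg": ("ge", both(150.0)),
            "hdl": ("le", both(59.0)),
            "bp": ("orge", {"sbp": 120.0, "dbp": 80.0}),
            "glucose": ("ge", both(100.0)),
        },
    }


@dataclass
class RiskThresholdConfig:
    factor_cuts: dict = field(default_factory=_default_cuts)
    mets: dict = field(default_factory=_default_mets)

    def __post_init__(self):
        for fac, (direction, cuts) in self.factor_cuts.items():
            for sex in ("male", "female"):
                lo, hi = cuts["low"][sex], cuts["high"][sex]
                ok = lo <= hi if direction == "ge" else lo >= hi
                if not ok:
                    raise ValueError(
                        f"{fac}: low-risk cutoff stricter than high-risk ({lo} vs {hi})"
                    )


def _compare(values: pd.Series, cut: np.ndarray | float, direction: str) -> pd.Series:
    """Tri-state comparison as a pandas nullable boolean Series."""
    v = pd.to_numeric(values, errors="coerce")
    if direction == "ge":
        res = v >= cut
    elif direction == "le":
        res = v <= cut
    else:
        raise ValueError(f"unknown direction {direction!r}")
    out = res.astype("boolean")
    out[v.isna()] = pd.NA
    return out


def _sex_cut(records: pd.DataFrame, cuts: dict) -> np.ndarray:
    sex = records["sex"].astype(str).str.lower().str[0]
    return np.where(sex == "m", cuts["male"], cuts["female"])


def label_factor(records: pd.DataFrame, factor: str, severity: str,
                 config: RiskThresholdConfig | None = None) -> pd.Series:
    """Tri-state at-risk label for one factor at one severity."""
    config = config or RiskThresholdConfig()
    if factor not in config.factor_cuts:
        raise KeyError(f"unknown factor {factor!r}")
    direction, cuts = config.factor_cuts[factor]
    cut = _sex_cut(records, cuts[severity])
    return _compare(records[factor], cut, direction).rename(f"{factor}_{severity}")


def _or_label(a: pd.Series, b: pd.Series) -> pd.Series:
    """Tri-state OR: true if either is true; missing unless falseness is
    established for every unobserved component."""
    out = a | b  # pandas Kleene logic: True|NA = True, False|NA = NA
    return out


def label_high_blood_pressure(records: pd.DataFrame, severity: str,
                              config: RiskThresholdConfig | None = None) -> pd.Series:
    """At risk iff SBP and/or DBP exceeds its cutoff; Kleene missingness.

    One present, at-risk component decides the label; an absent component
    with the present one below cutoff leaves the label missing.
    """
    config = config or RiskThresholdConfig()
    s = label_factor(records, "sbp", severity, config)
    d = label_factor(records, "dbp", severity, config)
    return _or_label(s, d).rename(f"high_bp_{severity}")


def _mets_components(records: pd.DataFrame, variant: str,
                     config: RiskThresholdConfig) -> pd.DataFrame:
    comp = config.mets[variant]
    out = {}
    for name, (direction, cuts) in comp.items():
        if direction == "orge":
            s = _compare(records["sbp"], cuts["sbp"], "ge")
            d = _compare(records["dbp"], cuts["dbp"], "ge")
            out[name] = _or_label(s, d)
        else:
            cut = _sex_cut(records, cuts)
            src = name if name in records.columns else name
            out[name] = _compare(records[src], cut, direction)
    return pd.DataFrame(out, index=records.index)


def label_mets(records: pd.DataFrame, variant: str,
               config: RiskThresholdConfig | None = None) -> pd.Series:
    """Metabolic syndrome: at risk iff >= 3 of the 5 components at risk;
    missing unless all five components are determinable."""
    config = config or RiskThresholdConfig()
    if variant not in ("low", "high"):
        raise ValueError("variant must be 'low' or 'high'")
    comps = _mets_components(records, variant, config)
    k = config.mets["k"]
    n_at_risk = comps.sum(axis=1, skipna=True)
    any_missing = comps.isna().any(axis=1)
    out = (n_at_risk >= k).astype("boolean")
    out[any_missing] = pd.NA
    return out.rename(f"mets_{variant}")


def label_all(records: pd.DataFrame,
              config: RiskThresholdConfig | None = None) -> pd.DataFrame:
    """All tri-state labels, indexed like the input, with a seqn column."""
    config = config or RiskThresholdConfig()
    out = pd.DataFrame({"seqn": records["seqn"]}, index=records.index)
    for fac in FACTOR_OUTCOMES:
        for sev in SEVERITIES:
            out[f"{fac}_{sev}"] = label_factor(records, fac, sev, config)
    for sev in SEVERITIES:
        out[f"high_bp_{sev}"] = label_high_blood_pressure(records, sev, config)
        out[f"mets_{sev}"] = label_mets(records, sev, config)
    return out


def label_counts(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome control / case / missing counts."""
    rows = []
    for col in labels.columns:
        if col == "seqn":
            continue
        s = labels[col]
        rows.append(
            {
                "outcome": col,
                "cases": int((s == True).sum()),      # noqa: E712 (Kleene)
                "controls": int((s == False).sum()),  # noqa: E712
                "missing": int(s.isna().sum()),
            }
        )
    return pd.DataFrame(rows)
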