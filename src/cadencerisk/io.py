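"""CSV (and optional SAS-XPT) readers/writers for the pipeline's tables.

Native interchange schemas
--------------------------
minute CSV:    seqn,day,minute,counts,steps,paxstat,paxcal
               (minute 0-based from midnight; day 1-based)
biomarker CSV: seqn,age,sex,smoking,bmi,waist,sbp,dbp,tg,hdl,glucose,
               weight,stratum,psu  (empty fields are missing, never 0)

Strict parsing reports malformed rows with their file line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "MINUTE_COLUMNS",
    "BIOMARKER_COLUMNS",
    "read_minute_csv",
    "read_biomarker_csv",
    "write_minute_csv",
    "write_biomarker_csv",
    "read_nhanes_paxraw_xpt",
]

MINUTE_COLUMNS = ("seqn", "day", "minute", "counts", "steps", "paxstat", "paxcal")
BIOMARKER_COLUMNS = ("seqn", "age", "sex", "smoking", "bmi", "waist", "sbp",
                     "dbp", "tg", "hdl", "glucose", "weight", "stratum", "psu")

_BIOMARKER_NUMERIC = ("age", "bmi", "waist", "sbp", "dbp", "tg", "hdl",
                      "glucose", "weight")


class SchemaError(ValueError):
    """Header does not match the expected schema."""


class ParseError(ValueError):
    """A row failed to parse; the message names the file line."""


def _check_header(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _bad_lines(series: pd.Series, converted: pd.Series) -> list:
    """File line numbers (1-based incl. header) of non-empty unparsable cells."""
    raw = series.astype(str).str.strip()
    bad = converted.isna() & (raw != "") & (raw.str.lower() != "nan")
    return [int(i) + 2 for i in np.nonzero(bad.to_numpy())[0]]


def read_minute_csv(path, strict: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    _check_header(df, MINUTE_COLUMNS, path)
    out = {}
    for col in MINUTE_COLUMNS:
        conv = pd.to_numeric(df[col], errors="coerce")
        bad = _bad_lines(df[col], conv)
        if (bad or conv.isna().any()) and strict:
            lines = bad or [int(i) + 2 for i in np.nonzero(conv.isna().to_numpy())[0][:5]]
            raise ParseError(f"{path}: non-numeric or empty '{col}' at line(s) {lines[:5]}")
        out[col] = conv
    res = pd.DataFrame(out)
    if strict:
        res = res.astype(np.int64)
        if (res[["counts", "steps"]] < 0).any().any():
            raise ParseError(f"{path}: negative counts/steps")
    else:
        res = res.dropna().astype(np.int64)
    return res


def read_biomarker_csv(path, strict: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    _check_header(df, BIOMARKER_COLUMNS, path)
    out = pd.DataFrame()
    for col in ("seqn", "stratum", "psu"):
        conv = pd.to_numeric(df[col], errors="coerce")
        if strict and conv.isna().any():
            raise ParseError(f"{path}: missing/invalid '{col}' "
                             f"at line(s) {_bad_lines(df[col], conv)[:5] or '(empty)'}")
        out[col] = conv.astype(np.int64)
    # empty string means missing, never zero
    for col in _BIOMARKER_NUMERIC:
        conv = pd.to_numeric(df[col], errors="coerce")
        bad = _bad_lines(df[col], conv)
        if strict and bad:
            raise ParseError(f"{path}: non-numeric '{col}' at line(s) {bad[:5]}")
        out[col] = conv
    sex = df["sex"].astype(str).str.strip().str.lower()
    sexmap = {"m": "male", "male": "male", "1": "male",
              "f": "female", "female": "female", "2": "female"}
    if strict and (~sex.isin(sexmap)).any():
        bad = [int(i) + 2 for i in np.nonzero((~sex.isin(sexmap)).to_numpy())[0]]
        raise ParseError(f"{path}: unrecognized 'sex' at line(s) {bad[:5]}")
    out["sex"] = sex.map(sexmap)
    smk = df["smoking"].astype(str).str.strip().str.lower()
    smkmap = {"1": 1, "yes": 1, "y": 1, "true": 1, "0": 0, "no": 0, "n": 0,
              "false": 0, "": np.nan}
    if strict and (~smk.isin(smkmap)).any():
        bad = [int(i) + 2 for i in np.nonzero((~smk.isin(smkmap)).to_numpy())[0]]
        raise ParseError(f"{path}: unrecognized 'smoking' at line(s) {bad[:5]}")
    out["smoking"] = smk.map(smkmap)
    return out[list(BIOMARKER_COLUMNS)]


def write_minute_csv(df: pd.DataFrame, path) -> None:
    df[list(MINUTE_COLUMNS)].to_csv(path, index=False)


def write_biomarker_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["smoking"] = out["smoking"].map(lambda v: "" if pd.isna(v) else int(v))
    out[list(BIOMARKER_COLUMNS)].to_csv(path, index=False)


def read_nhanes_paxraw_xpt(path) -> pd.DataFrame:
    """Adapter for a national-survey SAS transport accelerometer file.

    Maps SEQN/PAXDAY/PAXN/PAXINTEN/PAXSTEP/PAXSTAT/PAXCAL onto the native
    minute schema (PAXN is 1-based within day; PAXCAL/PAXSTAT code 1 = ok).
    """
    raw = pd.read_sas(path, format="xport")
    raw.columns = [c.upper() for c in raw.columns]
    need = ["SEQN", "PAXDAY", "PAXN", "PAXINTEN", "PAXSTEP", "PAXSTAT", "PAXCAL"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing variable(s) {missing}")
    out = pd.DataFrame(
        {
            "seqn": raw["SEQN"].astype(np.int64),
            "day": raw["PAXDAY"].astype(np.int64),
            "minute": ((raw["PAXN"].astype(np.int64) - 1) % 1440),
            "counts": raw["PAXINTEN"].astype(np.int64),
            "steps": raw["PAXSTEP"].astype(np.int64),
            "paxstat": (raw["PAXSTAT"] == 1).astype(np.int64),
            "paxcal": (raw["PAXCAL"] == 1).astype(np.int64),
        }
    )
    return out.sort_values(["seqn", "day", "minute"], kind="mergesort").reset_index(drop=True)
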