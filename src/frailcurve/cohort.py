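"""Load, harmonize and filter pooled two-source cohorts.

Covers the plumbing around the pooled cross-sectional analysis: typed CSV/TSV
loading with coercion warnings, cholesterol unit harmonization between
sources (mg/dL vs mmol/L), the non-HDL-C arithmetic (total cholesterol minus
HDL-C), and eligibility filtering (aged 65+, lipids present, at least 75% of
deficit items assessed) with an auditable exclusion log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CHOLESTEROL_MGDL_PER_MMOL",
    "load_cohort",
    "harmonize_units",
    "compute_non_hdl",
    "add_non_hdl",
    "apply_eligibility",
    "ExclusionLog",
]

#: molar conversion for cholesterol (1 mmol/L = 38.67 mg/dL)
CHOLESTEROL_MGDL_PER_MMOL = 38.67

#: lifestyle columns dropped at load: they confound the lipid exposure and
#: are excluded from this analysis by design
DROPPED_AT_LOAD = {"smoking", "alcohol", "diet", "dietary_pattern", "self_reported_hyperlipidemia"}

MANDATORY_COLUMNS = ["id", "age", "total_cholesterol", "hdl_c"]

_NUMERIC_COLUMNS = [
    "age", "total_cholesterol", "hdl_c", "non_hdl_c", "bun", "glucose", "creatinine",
    "hba1c", "uric_acid", "wbc", "hemoglobin", "mcv", "hct", "plt", "bmi", "waist",
]

CHOLESTEROL_COLUMNS = ["total_cholesterol", "hdl_c", "non_hdl_c"]


def load_cohort(path: str | Path, schema: dict[str, str] | None = None,
                sep: str | None = None) -> pd.DataFrame:
    """Load a cohort table from CSV/TSV.

    ``schema`` maps file column names to canonical names (identity when
    omitted).  Numeric columns are coerced; unparseable non-empty cells
    become missing and are counted in ``df.attrs['n_coercion_warnings']``
    (also emitted as a logging warning).  Raises on missing mandatory
    columns or duplicate ids.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if schema:
        df = df.rename(columns=schema)
    df = df.drop(columns=[c for c in df.columns if c.lower() in DROPPED_AT_LOAD])

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids: {dupes[:5]}")

    n_warnings = 0
    numeric = [c for c in df.columns if c in _NUMERIC_COLUMNS or c.startswith("item_")]
    for col in numeric:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.str.strip() != "")
        n_warnings += int(bad.sum())
        df[col] = coerced.astype(float)
    if n_warnings:
        log.warning("%d unparseable cells coerced to missing while loading %s", n_warnings, path)
    df.attrs["n_coercion_warnings"] = n_warnings
    return df


def harmonize_units(cohort: pd.DataFrame, unit: str | None = None) -> pd.DataFrame:
    """Convert cholesterol fields to mg/dL.

    The unit comes from a ``cholesterol_unit`` column if present, else the
    ``unit`` argument ("mg/dL" or "mmol/L").  Already-converted records
    (flag "mg/dL") pass through unchanged, making the operation idempotent.
    """
    out = cohort.copy()
    if "cholesterol_unit" in out.columns:
        flags = out["cholesterol_unit"].astype(str)
    elif unit is not None:
        flags = pd.Series([unit] * len(out), index=out.index)
    else:
        flags = pd.Series(["mg/dL"] * len(out), index=out.index)
    known = flags.isin(["mg/dL", "mmol/L"])
    if not known.all():
        raise ValueError(f"unknown cholesterol unit flag(s): {sorted(set(flags[~known]))}")
    to_convert = flags == "mmol/L"
    for col in CHOLESTEROL_COLUMNS:
        if col in out.columns:
            out.loc[to_convert, col] = out.loc[to_convert, col] * CHOLESTEROL_MGDL_PER_MMOL
    out["cholesterol_unit"] = "mg/dL"
    return out


def compute_non_hdl(total_cholesterol: float, hdl_c: float) -> float:
    """Non-HDL cholesterol: total cholesterol minus HDL-C (mg/dL).

    Raises if either input is missing or negative; a negative *result*
    (HDL above total cholesterol, a data anomaly) is returned and left to
    the caller to flag.
    """
    for name, v in (("total_cholesterol", total_cholesterol), ("hdl_c", hdl_c)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"{name} is missing")
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return float(total_cholesterol) - float(hdl_c)


def add_non_hdl(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive ``non_hdl_c`` (= TC - HDL) and flag anomalous negatives in
    ``non_hdl_anomalous``; rows with a missing input get a missing result."""
    out = cohort.copy()
    out["non_hdl_c"] = out["total_cholesterol"] - out["hdl_c"]
    out["non_hdl_anomalous"] = out["non_hdl_c"] < 0
    return out


@dataclass
class ExclusionLog:
    """Audit of eligibility filtering: per-rule counts (fixed rule order
    age -> labs -> completion) and each excluded record's first failing rule."""

    n_input: int
    n_retained: int
    counts: dict[str, int]
    first_failing: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        assert self.n_retained + sum(self.counts.values()) == self.n_input

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [f"rule\tcount"] + [f"{r}\t{c}" for r, c in self.counts.items()]
        rows.append(f"retained\t{self.n_retained}")
        path.write_text("\n".join(rows) + "\n")
        return path

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_retained": self.n_retained, "excluded": self.counts},
            indent=2,
        )


RULE_ORDER = ("age", "labs", "completion", "anomalous_non_hdl")


def apply_eligibility(
    cohort: pd.DataFrame,
    min_age: float = 65.0,
    min_completion: float = 0.75,
    item_cols: list[str] | None = None,
    drop_anomalous: bool = False,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the cohort eligibility rules and log exclusions.

    Retains records with age >= ``min_age`` ("over 65" includes 65 itself),
    non-missing total and HDL cholesterol, and a deficit completion fraction
    of at least ``min_completion`` (30 of 40 items passes).  Each excluded
    record is attributed to its *first* failing rule in the fixed order
    age -> labs -> completion (-> anomalous non-HDL when ``drop_anomalous``).
    """
    if item_cols is None:
        item_cols = [c for c in cohort.columns if c.startswith("item_")]
    fail_age = ~(cohort["age"] >= min_age)
    fail_labs = cohort["total_cholesterol"].isna() | cohort["hdl_c"].isna()
    if item_cols:
        completion = cohort[item_cols].notna().sum(axis=1) / len(item_cols)
    else:
        completion = pd.Series(1.0, index=cohort.index)
    fail_completion = completion < min_completion
    fail_anomalous = pd.Series(False, index=cohort.index)
    if drop_anomalous:
        fail_anomalous = (cohort["total_cholesterol"] - cohort["hdl_c"]) < 0

    first = pd.Series(pd.NA, index=cohort.index, dtype=object)
    for rule, mask in (("age", fail_age), ("labs", fail_labs),
                       ("completion", fail_completion), ("anomalous_non_hdl", fail_anomalous)):
        first[first.isna() & mask] = rule
    retained = cohort[first.isna()].copy()
    counts = {rule: int((first == rule).sum()) for rule in RULE_ORDER
              if rule != "anomalous_non_hdl" or drop_anomalous}
    excluded_first = first[first.notna()]
    if "id" in cohort.columns:
        excluded_first = excluded_first.set_axis(cohort.loc[excluded_first.index, "id"])
    return retained, ExclusionLog(len(cohort), len(retained), counts, excluded_first)
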