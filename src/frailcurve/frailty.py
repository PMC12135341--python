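"""Deficit-accumulation frailty index: item scoring, FI computation, categories.

The frailty index (FI) is the ratio of health deficits present to deficits
assessed, a continuous score in [0, 1].  Items may be binary, ordinal (scored
on an evenly spaced grid including 0 and 1) or thresholds on a continuous
measurement.  Missing or refused responses are excluded from the denominator
— they are never imputed as zero — and a record is only categorizable when at
least 75% of the items were assessed (configurable).

Categories follow the standard deficit-accumulation cut-points: non-frail
(FI <= 0.12), pre-frail (0.12 < FI < 0.25), frail (FI >= 0.25).  For the
dichotomous analyses the pre-frail and non-frail groups are merged, so
``frail_binary`` is 1 exactly when FI >= 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DeficitItemDef",
    "FrailtyResult",
    "NON_FRAIL",
    "PRE_FRAIL",
    "FRAIL",
    "score_item",
    "compute_fi",
    "categorize_fi",
    "dichotomize",
    "default_items",
    "items_to_yaml",
    "items_from_yaml",
    "add_fi_columns",
]

NON_FRAIL = "non-frail"
PRE_FRAIL = "pre-frail"
FRAIL = "frail"

DOMAINS = ("physical function", "psychological", "illness", "other health")

#: responses treated as missing rather than as any score
REFUSAL_TOKENS = {None, "", "refused", "dont_know", "don't know", "dk", "missing"}


@dataclass(frozen=True)
class DeficitItemDef:
    """One deficit item: its health domain, response kind and score mapping.

    ``kind`` is one of:

    - ``binary``: ``mapping`` maps responses to {0, 1};
    - ``ordinal``: ``mapping`` maps ordered responses onto an increasing
      grid in [0, 1] that includes 0 and 1 (default 5-level grid
      {0, 0.25, 0.5, 0.75, 1});
    - ``threshold``: ``mapping`` holds ``cutoff`` and ``direction``
      ("above"/"below"); a continuous raw value is a deficit (1.0) when it
      lies on the flagged side of the cutoff.
    """

    name: str
    domain: str
    kind: str
    mapping: dict

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.kind not in {"binary", "ordinal", "threshold"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "threshold":
            if not {"cutoff", "direction"} <= set(self.mapping):
                raise ValueError("threshold items need 'cutoff' and 'direction'")
            if self.mapping["direction"] not in {"above", "below"}:
                raise ValueError("direction must be 'above' or 'below'")
        else:
            vals = sorted(float(v) for v in self.mapping.values())
            if vals and (vals[0] < 0.0 or vals[-1] > 1.0):
                raise ValueError("score mapping range must lie within [0, 1]")
            if self.kind == "binary" and not set(vals) <= {0.0, 1.0}:
                raise ValueError("binary items must map to {0, 1}")
            if self.kind == "ordinal" and vals and (vals[0] != 0.0 or vals[-1] != 1.0):
                raise ValueError("ordinal grid must include 0 and 1")


@dataclass
class FrailtyResult:
    """FI for one participant: deficit sum, index, completion and category.

    ``category``/``frail_binary`` are ``None`` when the completion fraction
    falls below the required minimum (the record is reported, not errored,
    so the module is usable on unfiltered data).
    """

    n_total: int
    n_assessed: int
    deficit_sum: float
    fi: float
    completion: float
    category: str | None
    frail_binary: int | None

    @property
    def valid(self) -> bool:
        return self.category is not None


def _is_missing(raw: Any) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and math.isnan(raw):
        return True
    if isinstance(raw, str) and raw.strip().lower() in REFUSAL_TOKENS:
        return True
    return False


def score_item(item: DeficitItemDef, raw: Any) -> float:
    """Map a raw response to a deficit score in [0, 1], or NaN if missing.

    Unknown/refused responses become NaN (never 0); a response outside the
    item's declared domain raises ``ValueError``.
    """
    if _is_missing(raw):
        return float("nan")
    if item.kind == "threshold":
        value = float(raw)
        if item.mapping["direction"] == "above":
            return float(value > float(item.mapping["cutoff"]))
        return float(value < float(item.mapping["cutoff"]))
    if raw in item.mapping:
        return float(item.mapping[raw])
    # tolerate numeric/string coding mismatches ("1" vs 1 vs 1.0)
    for key, val in item.mapping.items():
        try:
            if float(key) == float(raw):
                return float(val)
        except (TypeError, ValueError):
            continue
    raise ValueError(f"response {raw!r} outside the declared domain of item {item.name!r}")


def compute_fi(scores: Sequence[float | None], min_completion: float = 0.75) -> FrailtyResult:
    """Compute the frailty index from a full-length list of optional scores.

    ``fi = sum(non-missing scores) / count(non-missing scores)``.  When the
    completion fraction is below ``min_completion`` the result carries no
    category (it is reported as invalid rather than raising).
    """
    if len(scores) == 0:
        raise ValueError("empty score list")
    arr = np.array([float("nan") if _is_missing(s) else float(s) for s in scores], dtype=float)
    n_total = arr.size
    assessed = ~np.isnan(arr)
    n_assessed = int(assessed.sum())
    if n_assessed == 0 and min_completion == 0:
        raise ValueError("all scores missing with min_completion=0: FI undefined")
    deficit_sum = float(arr[assessed].sum())
    fi = deficit_sum / n_assessed if n_assessed else float("nan")
    completion = n_assessed / n_total
    if completion >= min_completion and n_assessed > 0:
        category = categorize_fi(fi)
        frail = dichotomize(category)
    else:
        category, frail = None, None
    return FrailtyResult(n_total, n_assessed, deficit_sum, fi, completion, category, frail)


def categorize_fi(fi: float) -> str:
    """Three-level frailty category from FI: boundaries 0.12 (non-frail) and
    0.25 (frail) are inclusive on the outer categories."""
    if not 0.0 <= fi <= 1.0:
        raise ValueError(f"fi={fi} outside [0, 1]")
    if fi <= 0.12:
        return NON_FRAIL
    if fi < 0.25:
        return PRE_FRAIL
    return FRAIL


def dichotomize(category: str) -> int:
    """Merge pre-frail into non-frail: frail -> 1, everything else -> 0."""
    if category == FRAIL:
        return 1
    if category in {PRE_FRAIL, NON_FRAIL}:
        return 0
    raise ValueError(f"invalid category {category!r}")


# ---------------------------------------------------------------------------
# Default 40-item schema
# ---------------------------------------------------------------------------

_PHYSICAL = [
    "difficulty_walking_quarter_mile", "difficulty_climbing_stairs", "difficulty_stooping",
    "difficulty_lifting_10lb", "difficulty_standing_from_chair", "difficulty_dressing",
    "difficulty_eating", "difficulty_bathing", "difficulty_bed_transfer",
    "difficulty_household_chores", "difficulty_shopping", "limited_usual_activities",
]
_PSYCH = [
    "felt_depressed", "felt_everything_effort", "sleep_restless", "felt_lonely",
    "felt_fearful", "little_interest_in_things", "poor_concentration", "felt_hopeless",
]
_ILLNESS = [
    "hypertension_dx", "diabetes_dx", "heart_disease_dx", "stroke_dx", "arthritis_dx",
    "chronic_lung_disease_dx", "cancer_dx", "kidney_disease_dx", "liver_disease_dx",
    "asthma_dx",
]
_OTHER = [
    "self_rated_health_poor", "hospitalized_past_year", "falls_past_year",
    "vision_problem", "hearing_problem", "pain_interference", "unintentional_weight_loss",
    "memory_problem", "incontinence", "dental_problem",
]


def default_items(n_items: int = 40) -> list[DeficitItemDef]:
    """The shipped 40-item deficit schema spanning four health domains.

    All items are binary (responses pre-dichotomized as 0/1 or "no"/"yes");
    the scoring engine also supports ordinal and threshold items supplied
    via a custom schema document.
    """
    binary_map = {0: 0.0, 1: 1.0, "no": 0.0, "yes": 1.0}
    names_domains = (
        [(n, "physical function") for n in _PHYSICAL]
        + [(n, "psychological") for n in _PSYCH]
        + [(n, "illness") for n in _ILLNESS]
        + [(n, "other health") for n in _OTHER]
    )
    items = [DeficitItemDef(name, domain, "binary", dict(binary_map))
             for name, domain in names_domains]
    if n_items > len(items):
        raise ValueError(f"default schema has only {len(items)} items")
    return items[:n_items]


def items_to_yaml(items: Sequence[DeficitItemDef], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"name": it.name, "domain": it.domain, "kind": it.kind,
         "mapping": {str(k): v for k, v in it.mapping.items()}}
        for it in items
    ]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def items_from_yaml(path: str | Path) -> list[DeficitItemDef]:
    payload = yaml.safe_load(Path(path).read_text())
    return [DeficitItemDef(d["name"], d["domain"], d["kind"], d["mapping"]) for d in payload]


def add_fi_columns(
    cohort: pd.DataFrame,
    item_cols: Sequence[str] | None = None,
    min_completion: float = 0.75,
) -> pd.DataFrame:
    """Append ``fi``, ``fi_completion``, ``fi_category`` and ``frail_binary``
    columns computed from already-scored item columns (vectorized)."""
    out = cohort.copy()
    if item_cols is None:
        item_cols = [c for c in cohort.columns if c.startswith("item_")]
    if not item_cols:
        raise ValueError("no deficit item columns found")
    block = out[list(item_cols)].to_numpy(dtype=float)
    assessed = (~np.isnan(block)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        fi = np.nansum(block, axis=1) / assessed
    completion = assessed / len(item_cols)
    valid = (completion >= min_completion) & (assessed > 0)
    category = np.full(len(out), None, dtype=object)
    category[valid & (fi <= 0.12)] = NON_FRAIL
    category[valid & (fi > 0.12) & (fi < 0.25)] = PRE_FRAIL
    category[valid & (fi >= 0.25)] = FRAIL
    out["fi"] = fi
    out["fi_completion"] = completion
    out["fi_category"] = category
    out["frail_binary"] = np.where(valid, (fi >= 0.25).astype(float), np.nan)
    return out
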