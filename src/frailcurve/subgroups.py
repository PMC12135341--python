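"""Subgroup associations, interaction tests, between-source heterogeneity
and sensitivity refits.

Subgroup analysis stratifies the exposure-frailty association by sex, race,
education and age band (65-74 vs 75+) with per-stratum adjusted logistic
odds ratios; interaction is tested with a likelihood-ratio test on the
exposure x stratifier product terms in the pooled model.  Between-source
heterogeneity of the continuous FI is quantified with a linear mixed model
carrying a random intercept per source; its between-group variance is the
heterogeneity measure.  The sensitivity refit repeats the polynomial-logit
order selection after excluding participants with cardiometabolic
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .nonlinear import PolyFit, NadirResult, find_nadir, fit_polynomial_logit

log = logging.getLogger(__name__)

__all__ = [
    "SubgroupResult",
    "HeterogeneityResult",
    "add_age_band",
    "subgroup_analysis",
    "heterogeneity_mixed_model",
    "sensitivity_refit",
    "SensitivityComparison",
]


@dataclass
class SubgroupResult:
    stratifier: str
    stratum: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    interaction_p: float
    n: int


def add_age_band(cohort: pd.DataFrame, cut: float = 75.0) -> pd.DataFrame:
    """Append an ``age_band`` column: '65-74' below ``cut``, '75+' at/above."""
    out = cohort.copy()
    out["age_band"] = np.where(out["age"] >= cut, "75+", "65-74")
    return out


def _logit_fit(y: np.ndarray, X: np.ndarray):
    return sm.Logit(y, X).fit(disp=0, maxiter=500)


def _adjusted_design(df: pd.DataFrame, exposure: str, adjust: Sequence[str]) -> np.ndarray:
    cols = [df[exposure].astype(float).to_numpy()]
    for var in adjust:
        col = df[var]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        else:
            cols.append(col.astype(float).to_numpy())
    return sm.add_constant(np.column_stack(cols))


def subgroup_analysis(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    stratifiers: Sequence[str] = ("sex", "race", "education", "age_band"),
    adjust: Sequence[str] = (),
    min_stratum_size: int = 30,
) -> list[SubgroupResult]:
    """Per-stratum adjusted exposure odds ratios plus per-stratifier
    likelihood-ratio interaction tests.

    Strata that are empty, single-class or smaller than ``min_stratum_size``
    are skipped with a log entry.  The interaction p-value is shared by all
    strata of one stratifier (it tests the pooled product terms).
    """
    results: list[SubgroupResult] = []
    df = cohort.dropna(subset=[outcome, exposure]).copy()
    y_all = df[outcome].astype(int).to_numpy()

    for strat in stratifiers:
        counts = df[strat].value_counts()
        usable_levels = [lv for lv in counts.index if counts[lv] >= min_stratum_size
                         and df.loc[df[strat] == lv, outcome].nunique() == 2]
        dropped = [lv for lv in counts.index if lv not in usable_levels]
        if dropped:
            log.info("stratifier %s: excluding tiny/degenerate strata %s from the "
                     "interaction test", strat, dropped)
        pooled = df[df[strat].isin(usable_levels)]
        if len(usable_levels) < 2:
            log.info("stratifier %s has fewer than two usable strata; skipped", strat)
            continue
        interaction_p = _interaction_lrt(pooled, exposure, outcome, strat, adjust)
        for level, sub in df.groupby(strat, observed=True):
            y = sub[outcome].astype(int).to_numpy()
            if len(sub) < min_stratum_size or len(np.unique(y)) < 2:
                log.info("skipping stratum %s=%s (n=%d, degenerate or too small)",
                         strat, level, len(sub))
                continue
            adj = [a for a in adjust if a != strat and sub[a].nunique() > 1]
            X = _adjusted_design(sub, exposure, adj)
            try:
                res = _logit_fit(y, X)
            except Exception:
                log.info("skipping stratum %s=%s (fit failed)", strat, level)
                continue
            beta, se = float(res.params[1]), float(res.bse[1])
            z = stats.norm.ppf(0.975)
            results.append(SubgroupResult(
                strat, str(level), float(np.exp(beta)),
                (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
                float(res.pvalues[1]), interaction_p, len(sub),
            ))
    return results


def _interaction_lrt(df: pd.DataFrame, exposure: str, outcome: str,
                     stratifier: str, adjust: Sequence[str]) -> float:
    """LRT p-value for exposure x stratifier product terms in the pooled model."""
    y = df[outcome].astype(int).to_numpy()
    adj = [a for a in adjust if a != stratifier]
    base_cols = [df[exposure].astype(float).to_numpy()]
    strat_dummies = pd.get_dummies(df[stratifier], drop_first=True, dtype=float)
    for c in strat_dummies.columns:
        base_cols.append(strat_dummies[c].to_numpy())
    for var in adj:
        col = df[var]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            base_cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        else:
            base_cols.append(col.astype(float).to_numpy())
    X0 = sm.add_constant(np.column_stack(base_cols))
    inter_cols = [df[exposure].astype(float).to_numpy() * strat_dummies[c].to_numpy()
                  for c in strat_dummies.columns]
    X1 = np.column_stack([X0] + inter_cols)
    res0 = _logit_fit(y, X0)
    res1 = _logit_fit(y, X1)
    lr = 2.0 * (res1.llf - res0.llf)
    dof = X1.shape[1] - X0.shape[1]
    return float(stats.chi2.sf(max(lr, 0.0), dof))


@dataclass
class HeterogeneityResult:
    """Between-source variance of the FI from a random-intercept mixed model."""

    group_variance: float
    group_variance_se: float
    fixed_slope: float
    converged: bool

    def __post_init__(self) -> None:
        assert self.group_variance >= 0


def heterogeneity_mixed_model(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    group: str = "source",
    adjust: Sequence[str] = (),
) -> HeterogeneityResult:
    """Linear mixed model of the continuous FI on the exposure (plus
    covariates) with a random intercept per source.

    Reports the between-group (random-intercept) variance on the FI scale,
    its standard error and the fixed exposure slope (FI units per mg/dL).
    """
    df = cohort.dropna(subset=[outcome, exposure]).copy()
    if df[group].nunique() < 2:
        raise ValueError("need at least two groups")
    X = _adjusted_design(df, exposure, adjust)
    model = sm.MixedLM(df[outcome].astype(float).to_numpy(), X, groups=df[group].to_numpy())
    import warnings

    # with very few groups the default optimizer can stall at a spurious
    # positive variance; fit with several optimizers and keep the best
    # finite-likelihood solution
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "cg"):
            try:
                cand = model.fit(method=method) if method else model.fit()
            except Exception:
                continue
            if not np.isfinite(cand.llf):
                continue
            if res is None or cand.llf > res.llf:
                res = cand
    if res is None:
        raise RuntimeError("mixed model failed to converge with any optimizer")
    group_var = float(np.asarray(res.cov_re)[0, 0])
    # the "Group Var" entry of params/bse is on the scale-relative sqrt-free
    # parameterization; multiplying its bse by the residual scale recovers
    # the SE shown in the model summary
    try:
        group_var_se = float(np.asarray(res.bse)[-1] * res.scale)
    except Exception:
        group_var_se = float("nan")
    return HeterogeneityResult(
        group_variance=max(group_var, 0.0),
        group_variance_se=group_var_se,
        fixed_slope=float(res.fe_params[1]),
        converged=bool(res.converged),
    )


@dataclass
class SensitivityComparison:
    full_fit: PolyFit
    full_nadir: NadirResult
    reduced_fit: PolyFit
    reduced_nadir: NadirResult
    n_full: int
    n_reduced: int


def sensitivity_refit(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    drop_conditions: Sequence[str] = ("heart_disease", "diabetes", "hypertension", "stroke"),
    max_order: int = 4,
) -> SensitivityComparison:
    """Re-run the polynomial-logit order selection excluding participants
    flagged for any of ``drop_conditions``; report both selected fits and
    nadirs side by side."""
    missing = [c for c in drop_conditions if c not in cohort.columns]
    if missing:
        raise KeyError(f"condition columns not present: {missing}")
    df = cohort.dropna(subset=[outcome, exposure])
    y = df[outcome].astype(int).to_numpy()
    x = df[exposure].astype(float).to_numpy()
    keep = ~(df[list(drop_conditions)].fillna(0).astype(float) > 0).any(axis=1).to_numpy()
    if keep.sum() == 0:
        raise ValueError("exclusion removes every record")
    if len(np.unique(y[keep])) < 2:
        raise ValueError("exclusion empties an outcome class")

    _, full_fit = fit_polynomial_logit(y, x, max_order=max_order)
    _, red_fit = fit_polynomial_logit(y[keep], x[keep], max_order=max_order)
    rng_full = (float(x.min()), float(x.max()))
    rng_red = (float(x[keep].min()), float(x[keep].max()))
    return SensitivityComparison(
        full_fit, find_nadir(full_fit, rng_full),
        red_fit, find_nadir(red_fit, rng_red),
        n_full=len(y), n_reduced=int(keep.sum()),
    )
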