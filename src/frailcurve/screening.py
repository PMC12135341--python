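"""Variable screening cascade: univariate logistic associations, VIF-based
collinearity exclusion, gradient-boosted importance ranking, and
LASSO-penalized logistic retention.

The cascade runs in a fixed, auditable order: (1) variables with a variance
inflation factor above the threshold (default 10) are excluded — with the
lipid panel this removes HDL-C and total cholesterol, which are exactly
collinear with non-HDL-C; (2) a gradient-boosted tree ensemble ranks the
remaining variables by normalized split gain and categorical variables whose
importance falls below a low quantile are dropped; (3) an L1-penalized
logistic regression with cross-validated penalty choice zeroes out weak
coefficients; the surviving variables form the final covariate set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "UnivariateResult",
    "LassoResult",
    "ScreeningReport",
    "univariate_logistic",
    "compute_vif",
    "lasso_select",
    "boosted_importance",
    "run_screening",
    "BOOSTER_PARAMS",
]

#: fixed gradient-boosting hyperparameters used for importance ranking and
#: for the boosted risk model (no tuning loop anywhere in the pipeline)
BOOSTER_PARAMS: dict = {
    "n_estimators": 300,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "min_child_samples": 20,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "n_jobs": 1,
    "verbose": -1,
}


@dataclass
class UnivariateResult:
    """Odds ratio of a binary outcome per unit of one predictor (or one
    indicator contrast for a categorical level vs its reference)."""

    variable: str
    level: str | None
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    flag: str | None = None  # "degenerate" | "non-convergent" | None


def _fit_single_logit(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float] | None:
    X = sm.add_constant(x)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return None
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 50:
        return None
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


def univariate_logistic(
    outcome: Sequence[int],
    predictor: Sequence,
    reference_level: str | None = None,
    variable: str = "x",
) -> list[UnivariateResult]:
    """Univariate logistic association of a binary outcome with one predictor.

    Continuous predictors yield one result (OR = exp(slope), Wald 95% CI);
    categorical predictors expand to indicator contrasts against
    ``reference_level`` (default: most frequent level).  Degenerate
    (zero-variance) and separated/non-convergent fits are flagged instead of
    raising.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes")
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    pred = pd.Series(predictor)

    if pred.dtype == object or isinstance(pred.dtype, pd.CategoricalDtype):
        levels = pred.value_counts()
        ref = reference_level if reference_level is not None else levels.index[0]
        others = [lv for lv in levels.index if lv != ref]
        X = sm.add_constant(np.column_stack(
            [(pred == lv).astype(float).to_numpy() for lv in others]))
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            ok = res.mle_retvals.get("converged", False) and np.abs(res.params).max() <= 50
        except Exception:
            res, ok = None, False
        results = []
        z = stats.norm.ppf(0.975)
        for i, lv in enumerate(others, start=1):
            if not ok:
                results.append(UnivariateResult(variable, str(lv), None, None, None,
                                                flag="non-convergent"))
                continue
            beta, se = float(res.params[i]), float(res.bse[i])
            results.append(UnivariateResult(
                variable, str(lv), float(np.exp(beta)),
                (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
                float(res.pvalues[i]),
            ))
        return results
    x = pred.astype(float).to_numpy()
    return [_contrast_result(y, x, variable, None)]


def _contrast_result(y: np.ndarray, x: np.ndarray, variable: str, level: str | None) -> UnivariateResult:
    if np.nanstd(x) == 0:
        return UnivariateResult(variable, level, None, None, None, flag="degenerate")
    fit = _fit_single_logit(y, x)
    if fit is None:
        return UnivariateResult(variable, level, None, None, None, flag="non-convergent")
    beta, se, p = fit
    z = stats.norm.ppf(0.975)
    return UnivariateResult(
        variable, level, float(np.exp(beta)),
        (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))), p,
    )


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R²_j), with
    R²_j from an intercept-included OLS of column j on all other columns.
    Exactly collinear columns report ``inf``."""
    if design.shape[1] < 2:
        raise ValueError("need at least two columns")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more rows than columns")
    X = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class LassoResult:
    """L1-logistic screening outcome: coefficients on the original scale,
    the retained (nonzero) variables and the cross-validated penalty."""

    coefficients: pd.Series
    intercept: float
    retained: list[str]
    penalty: float


def lasso_select(
    outcome: Sequence[int],
    design: pd.DataFrame,
    penalty_grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> LassoResult:
    """LASSO-penalized logistic retention with CV-chosen penalty.

    The design is standardized internally; coefficients are reported back on
    the original scale.  The penalty (lambda = 1 / C in scikit-learn's
    parameterization) is chosen on ``penalty_grid`` (default: 50 log-spaced
    values in [1e-4, 10]) by minimum cross-validated deviance over
    ``folds`` stratified folds.  A penalty of exactly 0 fits the unpenalized
    maximum-likelihood model.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd

    if penalty_grid is None:
        penalty_grid = np.logspace(-4, 1, 50)
    penalty_grid = np.asarray(sorted(penalty_grid), dtype=float)

    if penalty_grid.size == 1 and penalty_grid[0] == 0.0:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = LogisticRegression(penalty=None, max_iter=5000, tol=1e-10)
            model.fit(Z, y)
        chosen = 0.0
    else:
        if np.any(penalty_grid <= 0):
            raise ValueError("penalty grid must be positive (or the single value 0)")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = LogisticRegressionCV(
                Cs=1.0 / penalty_grid, cv=cv, penalty="l1", solver="liblinear",
                scoring="neg_log_loss", max_iter=2000, tol=1e-8, random_state=seed,
            )
            model.fit(Z, y)
        chosen = float(1.0 / model.C_[0])

    w_std = model.coef_.ravel()
    w_orig = w_std / sd
    intercept = float(model.intercept_[0] - np.sum(w_std * mu / sd))
    coefs = pd.Series(w_orig, index=design.columns, name="coefficient")
    retained = [c for c in design.columns if coefs[c] != 0.0]
    return LassoResult(coefs, intercept, retained, chosen)


def boosted_importance(
    outcome: Sequence[int],
    design: pd.DataFrame,
    seed: int = 0,
) -> pd.Series:
    """Gradient-boosted variable importance (total split gain, normalized to
    sum 1), ranked descending with lexicographic tie-break."""
    from lightgbm import LGBMClassifier

    y = np.asarray(outcome, dtype=float)
    if len(y) < 100:
        raise ValueError("need at least 100 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    model = LGBMClassifier(random_state=seed, importance_type="gain", **BOOSTER_PARAMS)
    model.fit(design, y)
    gain = pd.Series(model.feature_importances_, index=design.columns, dtype=float)
    total = gain.sum()
    if total > 0:
        gain = gain / total
    order = sorted(gain.index, key=lambda v: (-gain[v], v))
    return gain.loc[order]


@dataclass
class ScreeningReport:
    """Full audit of the screening cascade."""

    univariate: list[UnivariateResult]
    vif: pd.Series
    vif_excluded: list[str]
    importance: pd.Series
    low_importance_dropped: list[str]
    lasso: LassoResult
    final_set: list[str]

    def to_json(self) -> str:
        return json.dumps({
            "vif": {k: (None if np.isinf(v) else v) for k, v in self.vif.items()},
            "vif_excluded": self.vif_excluded,
            "importance": self.importance.to_dict(),
            "low_importance_dropped": self.low_importance_dropped,
            "lasso_coefficients": self.lasso.coefficients.to_dict(),
            "lasso_penalty": self.lasso.penalty,
            "final_set": self.final_set,
        }, indent=2)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = ["variable\tlevel\todds_ratio\tci_low\tci_high\tp_value\tflag"]
        for r in self.univariate:
            ci = r.ci95 or (None, None)
            rows.append("\t".join(str(v) for v in
                                  (r.variable, r.level, r.odds_ratio, ci[0], ci[1], r.p_value, r.flag)))
        (directory / "univariate.tsv").write_text("\n".join(rows) + "\n")
        self.vif.to_csv(directory / "vif.tsv", sep="\t", header=True)
        self.importance.to_csv(directory / "importance.tsv", sep="\t", header=True)
        self.lasso.coefficients.to_csv(directory / "lasso.tsv", sep="\t", header=True)
        (directory / "screening.json").write_text(self.to_json())


def run_screening(
    cohort: pd.DataFrame,
    outcome: str,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
    vif_threshold: float = 10.0,
    low_importance_quantile: float = 0.10,
    seed: int = 0,
    protected: Sequence[str] = ("non_hdl_c",),
) -> ScreeningReport:
    """Run the full screening cascade on a cohort table.

    Order: VIF exclusion (> ``vif_threshold``) over the continuous design ->
    boosted importance ranking over survivors (+ integer-coded categoricals)
    -> drop categoricals below the ``low_importance_quantile`` of all
    importances -> LASSO pruning -> ``final_set``.

    Collinear variables are removed one at a time (highest VIF first,
    recomputing after each removal) until none exceeds the threshold.
    ``protected`` variables — by default the derived exposure, which is
    exactly collinear with its two lipid components — are never the ones
    removed, so the collinearity resolves by dropping the raw components.
    """
    df = cohort.dropna(subset=[outcome]).copy()
    y = df[outcome].astype(int).to_numpy()

    uni: list[UnivariateResult] = []
    for var in list(continuous) + list(categorical):
        uni.extend(univariate_logistic(y, df[var], variable=var))

    vif = compute_vif(df[list(continuous)])
    vif_excluded: list[str] = []
    survivors = list(continuous)
    current = vif
    while True:
        over = [v for v in survivors if current[v] > vif_threshold and v not in protected]
        if not over:
            break
        worst = max(over, key=lambda v: (current[v], v))
        vif_excluded.append(worst)
        survivors.remove(worst)
        if len(survivors) < 2:
            break
        current = compute_vif(df[survivors])

    design = df[survivors].copy()
    cat_codes = {}
    for var in categorical:
        codes = df[var].astype("category").cat.codes
        design[var] = codes
        cat_codes[var] = codes
    importance = boosted_importance(y, design, seed=seed)

    cutoff = importance.quantile(low_importance_quantile)
    low_dropped = [v for v in categorical if importance[v] < cutoff]

    lasso_vars = [v for v in design.columns if v not in low_dropped]
    lasso = lasso_select(y, design[lasso_vars], seed=seed)
    final_set = lasso.retained
    return ScreeningReport(uni, vif, vif_excluded, importance, low_dropped, lasso, final_set)
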