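"""Risk models for the dichotomized frailty outcome: multivariate logistic
and gradient-boosted classifiers on a stratified 70/30 split with stratified
5-fold cross-validation, plus ROC/AUC evaluation.

For a binary outcome the micro-averaged ROC coincides with the standard
ROC, so a single threshold-sweep curve is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .screening import BOOSTER_PARAMS

__all__ = [
    "SplitResult",
    "ModelBundle",
    "split_data",
    "fit_logistic",
    "fit_boosted",
    "cross_validate",
    "roc_and_auc",
]


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    empty_test: bool = False


def split_data(outcome: Sequence[int], train_fraction: float = 0.7, seed: int = 0) -> SplitResult:
    """Stratified train/test split on a binary outcome.

    Disjoint and exhaustive; per-class training counts are the class sizes
    times ``train_fraction``, rounded so the overall training size equals
    ``round(n * train_fraction)`` (largest-remainder rule, so class balance
    matches within one record per class).  ``train_fraction=1`` yields an
    empty, flagged test set.
    """
    y = np.asarray(outcome)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 records")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 records")
    rng = np.random.default_rng(seed)

    target_total = int(round(train_fraction * n))
    raw = counts * train_fraction
    base = np.floor(raw).astype(int)
    remainder = target_total - base.sum()
    order = np.argsort(-(raw - base))  # largest fractional part first
    for i in range(remainder):
        base[order[i % len(base)]] += 1

    train_parts = []
    for cls, k in zip(classes, base):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        train_parts.append(idx[:k])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    return SplitResult(train_idx, test_idx, empty_test=test_idx.size == 0)


@dataclass
class ModelBundle:
    """A fitted risk model plus its evaluation artifacts."""

    model_kind: str  # "logistic" | "boosted"
    variables: list[str]
    predict: Callable[[pd.DataFrame], np.ndarray] = field(repr=False)
    coefficients: pd.Series | None = None
    standard_errors: pd.Series | None = None
    flags: list[str] = field(default_factory=list)
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    cv_fold_aucs: list[float] | None = None
    test_auc: float | None = None
    roc_points: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps({
            "model_kind": self.model_kind,
            "variables": self.variables,
            "coefficients": None if self.coefficients is None else self.coefficients.to_dict(),
            "standard_errors": None if self.standard_errors is None else self.standard_errors.to_dict(),
            "flags": self.flags,
            "train_idx": None if self.train_idx is None else self.train_idx.tolist(),
            "test_idx": None if self.test_idx is None else self.test_idx.tolist(),
            "cv_fold_aucs": self.cv_fold_aucs,
            "test_auc": self.test_auc,
        }, indent=2)


def _design_matrix(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for var in variables:
        col = df[var]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=var, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[var] = col.astype(float)
    return X


def _drop_rank_deficient(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns that do not increase the design rank; returns
    the reduced design and the names of the dropped columns."""
    M = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in X.columns])
    if np.linalg.matrix_rank(M) == M.shape[1]:
        return X, []
    kept: list[str] = []
    dropped: list[str] = []
    base = np.ones((len(X), 1))
    for c in X.columns:
        cand = np.column_stack([base, X[c].to_numpy()])
        if np.linalg.matrix_rank(cand) > base.shape[1]:
            kept.append(c)
            base = cand
        else:
            dropped.append(c)
    return X[kept], dropped


def fit_logistic(train: pd.DataFrame, variables: Sequence[str], outcome: str) -> ModelBundle:
    """Maximum-likelihood logistic fit with intercept.

    Rank-deficient designs are reduced (the dropped columns are named in
    ``flags``); separation/non-convergence is flagged rather than raised.
    A constant outcome is an error.
    """
    y = train[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    X = _design_matrix(train, variables)
    X, dropped = _drop_rank_deficient(X)
    flags = [f"rank-deficient: dropped {c}" for c in dropped]
    design = sm.add_constant(X.to_numpy(dtype=float))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=500)
        except np.linalg.LinAlgError:
            # perfectly separated designs make the Newton Hessian singular;
            # a gradient-based fit still yields usable (huge) coefficients
            res = sm.Logit(y, design).fit(disp=0, maxiter=2000, method="bfgs")
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 100:
        flags.append("separation/non-convergence")
    names = ["intercept"] + list(X.columns)
    coefs = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    cols = list(X.columns)

    def predict(df: pd.DataFrame) -> np.ndarray:
        Xn = _design_matrix(df, variables)
        Xn = Xn.reindex(columns=cols, fill_value=0.0)
        return res.predict(sm.add_constant(Xn.to_numpy(dtype=float), has_constant="add"))

    return ModelBundle("logistic", list(variables), predict, coefs, bse, flags)


def fit_boosted(train: pd.DataFrame, variables: Sequence[str], outcome: str, seed: int = 0) -> ModelBundle:
    """Gradient-boosted classifier with the package's fixed hyperparameters."""
    from lightgbm import LGBMClassifier

    y = train[outcome].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    X = _design_matrix(train, variables)
    cols = list(X.columns)
    model = LGBMClassifier(random_state=seed, **BOOSTER_PARAMS)
    model.fit(X, y)

    def predict(df: pd.DataFrame) -> np.ndarray:
        Xn = _design_matrix(df, variables).reindex(columns=cols, fill_value=0.0)
        return model.predict_proba(Xn)[:, 1]

    return ModelBundle("boosted", list(variables), predict)


def cross_validate(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome: str,
    folds: int = 5,
    seed: int = 0,
    model_kind: str = "logistic",
) -> tuple[list[float], float]:
    """Stratified k-fold cross-validated AUC.

    Folds are disjoint and exhaustive; each fold's AUC comes from its
    held-out records.  Returns (per-fold AUCs, mean AUC).
    """
    y = cohort[outcome].astype(int).to_numpy()
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("a class is too small to stratify into the requested folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    df = cohort.reset_index(drop=True)
    for tr, te in cv.split(np.zeros(len(y)), y):
        if model_kind == "logistic":
            bundle = fit_logistic(df.iloc[tr], variables, outcome)
        else:
            bundle = fit_boosted(df.iloc[tr], variables, outcome, seed=seed)
        scores = bundle.predict(df.iloc[te])
        _, auc = roc_and_auc(scores, y[te])
        aucs.append(auc)
    return aucs, float(np.mean(aucs))


def roc_and_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep over the unique scores and trapezoid AUC.

    The trapezoid AUC equals the Mann-Whitney concordance statistic (ties
    counted 1/2) to floating precision.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
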