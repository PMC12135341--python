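"""U-shape detection: partial dependence, polynomial-logit fits with AIC
order selection, nadir location, and quartile-based risk ranges.

The dose-response between the exposure (non-HDL-C, mg/dL) and the
dichotomized frailty outcome is probed two ways:

1. *Partial dependence* of a fitted risk model: PD(v) is the mean predicted
   probability over the cohort with the exposure column forced to v.  It is
   a qualitative check — its argmin should fall inside the derived low-risk
   range.
2. *Polynomial logistic regression*: one logistic fit per polynomial order
   1..max_order of the exposure (centered and scaled internally for
   conditioning, coefficients reported back in mg/dL).  The order is chosen
   by AIC with a parsimony rule: among orders within ``aic_tolerance``
   (default 2) AIC units of the minimum, the lowest order wins.  AIC is
   defined as 2k - 2*log-likelihood with k = order + 1 fitted coefficients
   (intercept included).

For an order-2 fit with positive quadratic coefficient the nadir is the
vertex -b1/(2*b2); higher orders use derivative root-finding.  Risk ranges
mirror the quartile construction: the ideal range is the smallest interval
symmetric about the nadir holding >= 25% of the observations, and the two
high-risk tails run from the 0.5% trim point to the 12.5% quantile on each
side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial import Polynomial

from .modeling import ModelBundle

__all__ = [
    "PDPCurve",
    "PolyFit",
    "NadirResult",
    "RiskRanges",
    "partial_dependence",
    "default_grid",
    "fit_polynomial_logit",
    "find_nadir",
    "derive_risk_ranges",
]


@dataclass
class PDPCurve:
    grid: np.ndarray
    pd_values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.pd_values = np.asarray(self.pd_values, dtype=float)
        if self.grid.size == 0:
            raise ValueError("empty grid")
        if not np.all(np.diff(self.grid) > 0) and self.grid.size > 1:
            raise ValueError("grid must be strictly increasing")

    def argmin(self) -> float:
        return float(self.grid[int(np.argmin(self.pd_values))])

    def to_tsv(self, path) -> None:
        pd.DataFrame({"grid": self.grid, "pd": self.pd_values}).to_csv(path, sep="\t", index=False)


def default_grid(exposure: Sequence[float], n_points: int = 100) -> np.ndarray:
    """100 equally spaced points between the 1st and 99th exposure percentiles."""
    x = np.asarray(exposure, dtype=float)
    lo, hi = np.percentile(x, [1, 99])
    return np.linspace(lo, hi, n_points)


def partial_dependence(
    model: ModelBundle,
    feature: str,
    grid: Sequence[float],
    cohort: pd.DataFrame,
) -> PDPCurve:
    """PD(v) = mean predicted probability with ``feature`` forced to v for
    every record, all other fields untouched."""
    if feature not in model.variables:
        raise KeyError(f"{feature!r} not among model variables")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    values = np.empty(grid.size)
    work = cohort.copy()
    for i, v in enumerate(grid):
        work[feature] = v
        values[i] = float(np.mean(model.predict(work)))
    return PDPCurve(grid, values)


@dataclass
class PolyFit:
    """One polynomial-logit fit: coefficients in mg/dL (ascending degree),
    log-likelihood and AIC (2k - 2*llf, k = order + 1)."""

    order: int
    coefficients: np.ndarray  # on the original exposure scale, ascending
    log_likelihood: float
    aic: float
    converged: bool = True

    def logit_at(self, x: np.ndarray | float) -> np.ndarray | float:
        return Polynomial(self.coefficients)(x)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coefficients": list(map(float, self.coefficients)),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "converged": self.converged,
        }


def fit_polynomial_logit(
    outcome: Sequence[int],
    exposure: Sequence[float],
    max_order: int = 4,
    aic_tolerance: float = 2.0,
) -> tuple[list[PolyFit], PolyFit]:
    """Fit logistic models with raised-power exposure terms, orders
    1..max_order, and select an order by AIC.

    The exposure is centered/scaled internally; reported coefficients are
    back-transformed to the mg/dL scale.  Selection: lowest order whose AIC
    is within ``aic_tolerance`` of the minimum (``aic_tolerance=0`` gives
    the strict minimum-AIC rule; exact ties always go to the lower order).
    Non-convergent orders are flagged and skipped in selection.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    m, s = x.mean(), x.std()
    if s == 0:
        raise ValueError("exposure is constant")
    z = (x - m) / s

    fits: list[PolyFit] = []
    for order in range(1, max_order + 1):
        X = sm.add_constant(np.column_stack([z ** j for j in range(1, order + 1)]))
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=500)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res, converged = None, False
        if res is None:
            fits.append(PolyFit(order, np.full(order + 1, np.nan), np.nan, np.nan, converged=False))
            continue
        # back-transform: P(z) with z = (x - m)/s composed into powers of x
        poly_z = Polynomial(res.params)
        poly_x = poly_z(Polynomial([-m / s, 1.0 / s]))
        coefs = np.zeros(order + 1)
        coefs[: len(poly_x.coef)] = poly_x.coef
        k = order + 1
        aic = 2.0 * k - 2.0 * res.llf
        fits.append(PolyFit(order, coefs, float(res.llf), float(aic), converged=converged))

    usable = [f for f in fits if f.converged]
    if not usable:
        raise RuntimeError("no polynomial order converged")
    best_aic = min(f.aic for f in usable)
    selected = next(f for f in usable if f.aic <= best_aic + aic_tolerance)
    return fits, selected


@dataclass
class NadirResult:
    """Location of the fitted risk minimum, or the reason it is absent."""

    value: float | None
    reason: str | None = None


def find_nadir(fit: PolyFit, observed_range: tuple[float, float]) -> NadirResult:
    """Interior minimum of the fitted logit polynomial.

    Order 2 with positive quadratic coefficient: the vertex -b1/(2*b2).
    Higher orders: real roots of the derivative that are local minima; the
    lowest-valued one inside ``observed_range`` wins.  A concave order-2
    fit or a minimum outside the range yields an absent nadir with reason.
    """
    if fit.order < 2:
        return NadirResult(None, "order < 2: no curvature to locate")
    lo, hi = observed_range
    if fit.order == 2:
        b1, b2 = fit.coefficients[1], fit.coefficients[2]
        if b2 <= 0:
            return NadirResult(None, "no interior minimum (concave fit)")
        vertex = -b1 / (2.0 * b2)
        if not lo <= vertex <= hi:
            return NadirResult(None, "vertex outside observed exposure range")
        return NadirResult(float(vertex))
    # higher orders: locate interior minima on a dense grid (robust to the
    # repeated derivative roots that defeat polynomial root-finding), then
    # polish with Brent
    from scipy import optimize

    poly = Polynomial(fit.coefficients)
    grid = np.linspace(lo, hi, 2001)
    vals = poly(grid)
    interior = np.flatnonzero((vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:])) + 1
    if interior.size == 0:
        return NadirResult(None, "no interior minimum")
    candidates = []
    for i in interior:
        res = optimize.minimize_scalar(poly, bracket=None,
                                       bounds=(grid[i - 1], grid[i + 1]), method="bounded",
                                       options={"xatol": 1e-10})
        candidates.append(float(res.x))
    best = min(candidates, key=lambda v: poly(v))
    if not lo < best < hi:
        return NadirResult(None, "no interior minimum")
    return NadirResult(float(best))


@dataclass
class RiskRanges:
    """Exposure intervals: a central low-risk (ideal) interval symmetric
    about the nadir and two high-risk tails."""

    ideal: tuple[float, float]
    low_tail: tuple[float, float]
    high_tail: tuple[float, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not (self.low_tail[1] < self.ideal[0] and self.ideal[1] < self.high_tail[0]):
                raise ValueError("risk ranges must be disjoint and ordered")

    def to_json(self) -> str:
        return json.dumps({
            "ideal": list(self.ideal), "low_tail": list(self.low_tail),
            "high_tail": list(self.high_tail), "degenerate": self.degenerate,
        }, indent=2)


def derive_risk_ranges(
    exposure: Sequence[float],
    nadir: float,
    central_mass: float = 0.25,
    tail_mass: float = 0.125,
    trim: float = 0.005,
) -> RiskRanges:
    """Quartile-style risk ranges around the nadir.

    ideal = [nadir - w, nadir + w] with w the smallest half-width covering
    at least ``central_mass`` of the observations (so the ideal midpoint
    equals the nadir by construction); low_tail = [q(trim), q(tail_mass)];
    high_tail = [q(1 - tail_mass), q(1 - trim)].  ``central_mass=0`` yields
    a degenerate, flagged interval at the nadir.
    """
    x = np.asarray(exposure, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no exposure observations")
    if not x.min() <= nadir <= x.max():
        raise ValueError("nadir outside the observed exposure range")
    if not (0 <= central_mass < 1 and 0 < tail_mass < 1 and central_mass + 2 * tail_mass <= 1):
        raise ValueError("invalid central/tail masses")

    low_tail = (float(np.quantile(x, trim)), float(np.quantile(x, tail_mass)))
    high_tail = (float(np.quantile(x, 1 - tail_mass)), float(np.quantile(x, 1 - trim)))
    if central_mass == 0:
        return RiskRanges((nadir, nadir), low_tail, high_tail, degenerate=True)
    w = float(np.quantile(np.abs(x - nadir), central_mass))
    ideal = (nadir - w, nadir + w)
    if not (low_tail[1] < ideal[0] and ideal[1] < high_tail[0]):
        raise ValueError("insufficient data in a tail: ranges overlap")
    return RiskRanges(ideal, low_tail, high_tail)
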