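"""Synthetic two-source cohort generator with a known U-shaped exposure-frailty link.

The generator emulates a pooled cross-sectional cohort of adults aged 65+
drawn from two population health surveys (tagged ``NHANES`` and ``CHARLS``).
Each participant receives an atherogenic-cholesterol exposure (non-HDL-C,
mg/dL), a set of loosely correlated demographic/laboratory covariates, and
40 binary health-deficit responses.  Deficit probabilities are driven by a
latent liability that is *quadratic* in the exposure, so the true
exposure-frailty dose-response is U-shaped with a known nadir — the ground
truth every downstream recovery test measures against.

The liability for participant *i* is

    L_i = b0 + c * (x_i - nadir)^2 + sum_k beta_k * (z_ik - mu_k) + s * B_i

with exposure ``x_i``, curvature ``c`` (liability units per (mg/dL)^2),
centered covariates ``z_ik`` and a small between-source offset ``s`` for
source-B membership.  Deficit *j* is Bernoulli with probability
``expit(L_i + o_j)`` where the item offsets ``o_j`` are equally spaced on
the logit scale so item prevalences span roughly 5-60%.

Randomness is split into named substreams (exposure, covariates, items,
conditions) so that e.g. raising the curvature while holding the seed fixed
reuses the same item uniforms — deficit patterns then change monotonically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "SimulationParams",
    "LatentTruth",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "item_columns",
    "item_offsets",
    "DEFAULT_COVARIATE_EFFECTS",
    "COVARIATE_REFERENCE_MEANS",
]

#: marginal (mean, sd, lower clip, upper clip) loosely emulating the pooled
#: cohort's descriptive table; only the exposure-outcome structure is meant
#: to be faithful, the covariates just need realistic scales.
COVARIATE_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "age": (72.4, 5.4, 65.0, 100.0),
    "bmi": (26.2, 5.8, 13.0, 60.0),
    "waist": (94.6, 15.6, 50.0, 170.0),
    "glucose": (109.4, 33.0, 45.0, 400.0),
    "hba1c": (5.88, 0.91, 3.5, 16.0),
    "creatinine": (0.94, 0.31, 0.3, 4.0),
    "wbc": (6.64, 1.89, 1.5, 25.0),
    "hemoglobin": (13.77, 1.58, 7.0, 20.0),
    "hct": (40.9, 4.57, 20.0, 60.0),
    "mcv": (91.4, 6.37, 60.0, 120.0),
    "plt": (211.8, 61.6, 30.0, 600.0),
    "bun": (17.1, 5.9, 3.0, 60.0),
    "uric_acid": (5.38, 1.45, 1.0, 13.0),
    "hdl_c": (53.7, 15.0, 15.0, 120.0),
}

#: correlated covariate pairs (loose physiological coupling)
_CORRELATED_PAIRS = {("bmi", "waist"): 0.75, ("glucose", "hba1c"): 0.60, ("hemoglobin", "hct"): 0.85}

#: categorical marginals from pooled descriptive counts
RACE_LEVELS = ["asian", "african_american", "white", "latino_hispanic", "other"]
RACE_PROBS = np.array([4175, 921, 2871, 1033, 147], dtype=float)
EDUCATION_LEVELS = ["primary_or_below", "secondary", "higher"]
EDUCATION_PROBS = np.array([4753, 1786, 2608], dtype=float)
MARITAL_LEVELS = ["married", "unmarried", "widowed", "divorced"]
MARITAL_PROBS = np.array([5454, 2133, 739, 228], dtype=float)
CONDITION_PREVALENCE = {"hypertension": 0.45, "diabetes": 0.20, "heart_disease": 0.15, "stroke": 0.07}

#: reference means used to center covariates inside the liability
COVARIATE_REFERENCE_MEANS: dict[str, float] = {
    name: mean for name, (mean, _, _, _) in COVARIATE_MARGINALS.items()
}

#: default liability slopes per raw covariate unit (centered at reference
#: means); magnitudes give a combined covariate liability SD of ~0.5.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": 0.04,
    "bmi": 0.05,
    "waist": 0.01,
    "glucose": 0.004,
    "creatinine": 0.40,
    "wbc": 0.05,
    "hemoglobin": -0.10,
    "hba1c": 0.20,
    "sex_female": 0.15,
}


def item_columns(n_items: int = 40) -> list[str]:
    """Canonical deficit-item column names (``item_01`` .. ``item_40``)."""
    return [f"item_{i:02d}" for i in range(1, n_items + 1)]


def item_offsets(n_items: int = 40, prevalence_span: tuple[float, float] = (0.05, 0.60)) -> np.ndarray:
    """Item-specific logit offsets, equally spaced so that at zero liability
    item prevalences span ``prevalence_span``."""
    lo, hi = prevalence_span
    return np.linspace(logit(lo), logit(hi), n_items)


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters of the synthetic pooled cohort.

    ``exposure_mean``/``exposure_sd`` reproduce the pooled non-HDL-C
    marginal (134.9 +/- 36.7 mg/dL); ``nadir_true`` is the exposure value
    minimizing the deficit liability; ``curvature`` (>= 0) is the quadratic
    liability coefficient per (mg/dL)^2.  The default curvature 1.5e-4
    yields odds of frailty ~6x the nadir odds at |x - nadir| ~ 108 mg/dL
    (the printed high-risk tail distance) but only ~1.25x at ~38 mg/dL
    (the low-risk boundary), i.e. a pronounced but realistic U.
    ``baseline_liability`` is calibrated so frail prevalence is ~35%.
    """

    n_participants: int = 9000
    seed: int = 0
    exposure_mean: float = 134.9
    exposure_sd: float = 36.7
    exposure_bounds: tuple[float, float] = (40.0, 320.0)
    nadir_true: float = 156.09
    curvature: float = 1.5e-4
    baseline_liability: float = -0.9
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    source_shift: float = 0.15
    item_missing_rate: float = 0.0
    n_items: int = 40

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if self.curvature < 0:
            raise ValueError("curvature must be >= 0")
        if not 0.0 <= self.item_missing_rate <= 1.0:
            raise ValueError("item_missing_rate must lie in [0, 1]")
        lo, hi = self.exposure_bounds
        if not lo < hi:
            raise ValueError("exposure_bounds must be an increasing interval")
        if not lo < self.nadir_true < hi:
            raise ValueError("nadir_true must lie strictly inside exposure_bounds")
        if self.n_items <= 0:
            raise ValueError("n_items must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["exposure_bounds"] = list(d["exposure_bounds"])
        return json.dumps(d, indent=2)


@dataclass
class LatentTruth:
    """Per-participant ground truth: liability and its inverse-logit."""

    liability: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.liability = np.asarray(self.liability, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _correlated_pair(rng: np.random.Generator, n: int, name_a: str, name_b: str,
                     rho: float) -> tuple[np.ndarray, np.ndarray]:
    ma, sa, loa, hia = COVARIATE_MARGINALS[name_a]
    mb, sb, lob, hib = COVARIATE_MARGINALS[name_b]
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    a = np.clip(ma + sa * z[:, 0], loa, hia)
    b = np.clip(mb + sb * z[:, 1], lob, hib)
    return a, b


def generate_cohort(params: SimulationParams) -> tuple[pd.DataFrame, LatentTruth]:
    """Generate a pooled two-source cohort with a known U-shaped truth.

    Returns a table with one row per participant (demographics, labs, chronic
    condition flags, ``n_items`` binary deficit columns) and the latent truth
    (liability and inverse-logit probability) used to generate the deficits.
    Fixing ``params.seed`` fixes every generated value bit-for-bit.
    """
    params.validate()
    n = params.n_participants
    items = item_columns(params.n_items)
    if n == 0:
        cols = _column_order(params.n_items)
        return pd.DataFrame(columns=cols), LatentTruth(np.array([]), np.array([]))

    ss = np.random.SeedSequence(params.seed)
    rng_exposure, rng_cov, rng_items, rng_cond = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    lo, hi = params.exposure_bounds
    exposure = _truncated_normal(rng_exposure, params.exposure_mean, params.exposure_sd, lo, hi, n)

    cov: dict[str, np.ndarray] = {}
    paired = {name for pair in _CORRELATED_PAIRS for name in pair}
    for (a, b), rho in _CORRELATED_PAIRS.items():
        cov[a], cov[b] = _correlated_pair(rng_cov, n, a, b, rho)
    for name, (mean, sd, clo, chi) in COVARIATE_MARGINALS.items():
        if name in paired:
            continue
        if name == "age":
            cov[name] = _truncated_normal(rng_cov, mean, sd, clo, chi, n)
        else:
            cov[name] = np.clip(rng_cov.normal(mean, sd, size=n), clo, chi)

    sex = np.where(rng_cov.random(n) < 0.5, "female", "male")
    source = np.where(rng_cov.random(n) < 0.5, "NHANES", "CHARLS")
    cycle = np.where(source == "NHANES", "2009-2018", "2011/2015")
    race = rng_cov.choice(RACE_LEVELS, size=n, p=RACE_PROBS / RACE_PROBS.sum())
    education = rng_cov.choice(EDUCATION_LEVELS, size=n, p=EDUCATION_PROBS / EDUCATION_PROBS.sum())
    marital = rng_cov.choice(MARITAL_LEVELS, size=n, p=MARITAL_PROBS / MARITAL_PROBS.sum())

    conditions = {
        name: (rng_cond.random(n) < prev).astype(int)
        for name, prev in CONDITION_PREVALENCE.items()
    }

    liability = params.baseline_liability + params.curvature * (exposure - params.nadir_true) ** 2
    for name, slope in params.covariate_effects.items():
        if name == "sex_female":
            liability = liability + slope * (sex == "female").astype(float)
        elif name in cov:
            liability = liability + slope * (cov[name] - COVARIATE_REFERENCE_MEANS[name])
        else:
            raise KeyError(f"unknown covariate effect: {name!r}")
    liability = liability + params.source_shift * (source == "CHARLS").astype(float)

    offsets = item_offsets(params.n_items)
    u = rng_items.random((n, params.n_items))
    p_items = expit(liability[:, None] + offsets[None, :])
    responses = (u < p_items).astype(float)

    hdl = cov.pop("hdl_c")
    df = pd.DataFrame({
        "id": [f"S{i:06d}" for i in range(n)],
        "source": source,
        "cycle": cycle,
        "age": cov["age"],
        "sex": sex,
        "race": race,
        "education": education,
        "marital_status": marital,
        "hdl_c": hdl,
        "non_hdl_c": exposure,
        "total_cholesterol": exposure + hdl,
        "bun": cov["bun"],
        "glucose": cov["glucose"],
        "creatinine": cov["creatinine"],
        "hba1c": cov["hba1c"],
        "uric_acid": cov["uric_acid"],
        "wbc": cov["wbc"],
        "hemoglobin": cov["hemoglobin"],
        "mcv": cov["mcv"],
        "hct": cov["hct"],
        "plt": cov["plt"],
        "bmi": cov["bmi"],
        "waist": cov["waist"],
        **conditions,
    })
    for j, col in enumerate(items):
        df[col] = responses[:, j]
    df = df[_column_order(params.n_items)]

    truth = LatentTruth(liability=liability, probability=expit(liability))
    if params.item_missing_rate > 0:
        df = inject_missingness(df, params.item_missing_rate, seed=int(ss.generate_state(1)[0] >> 1))
    return df, truth


def _column_order(n_items: int) -> list[str]:
    return (
        ["id", "source", "cycle", "age", "sex", "race", "education", "marital_status",
         "total_cholesterol", "hdl_c", "non_hdl_c", "bun", "glucose", "creatinine",
         "hba1c", "uric_acid", "wbc", "hemoglobin", "mcv", "hct", "plt", "bmi", "waist"]
        + list(CONDITION_PREVALENCE)
        + item_columns(n_items)
    )


def inject_missingness(cohort: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set deficit responses missing completely at random with probability ``rate``.

    Non-deficit fields are untouched; the input frame is not modified.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    out = cohort.copy()
    items = [c for c in cohort.columns if c.startswith("item_")]
    if rate == 0.0 or not items or len(cohort) == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((len(cohort), len(items))) < rate
    block = out[items].to_numpy(dtype=float)
    block[mask] = np.nan
    out[items] = block
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path, params: SimulationParams | None = None) -> Path:
    """Write the cohort as CSV (missing deficits as empty fields) with an
    optional sidecar ``<path>.params.json`` recording the generating params."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    if params is not None:
        Path(str(path) + ".params.json").write_text(params.to_json())
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    return pd.read_csv(path, dtype={"id": str})
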