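# Methods

This note documents the statistical model behind `frailcurve`, the
synthetic-cohort generator that drives its validation, and the design
choices made where more than one defensible option existed.

## 1. Frailty index

The deficit-accumulation FI is the mean of item deficit scores over the
items actually assessed. Items are binary (0/1), ordinal (scored on an
evenly spaced grid containing 0 and 1 — for five levels
{0, 0.25, 0.5, 0.75, 1}), or thresholds on a continuous measurement.
Missing and refused responses are excluded from the denominator and are
never imputed as zero; a record is categorizable only when at least 75% of
the items were assessed (30 of 40 passes; 29 of 40 does not). Cut-points:
non-frail FI ≤ 0.12, pre-frail 0.12 < FI < 0.25, frail FI ≥ 0.25, with both
boundary values assigned to the outer categories. The dichotomous outcome
used by all risk models merges pre-frail into non-frail
(`frail_binary = 1 ⇔ FI ≥ 0.25`).

The shipped 40-item schema spans four domains (physical function,
psychological, illness, other health) with binary scoring. It is a
documented stand-in, not a claim of equivalence with any particular survey
instrument: the FI methodology is robust to the precise item composition,
and the schema is fully configurable through a YAML document.

## 2. Synthetic cohort generator

The generator emulates a pooled two-source cross-sectional cohort
(sources tagged NHANES/CHARLS) of adults aged 65+. Its purpose is to give
every downstream stage a known ground truth; only the exposure–outcome
structure is meant to be faithful. Per participant *i*:

- exposure `x_i` ~ truncated Normal(134.9, 36.7²) on [40, 320] mg/dL;
- covariates (age, BMI, waist, glucose, HbA1c, creatinine, WBC,
  hemoglobin, HCT, MCV, platelets, BUN, uric acid, HDL-C) drawn from
  documented marginals on the scales of a typical pooled elderly cohort,
  with a few loose physiological couplings (BMI–waist r = 0.75,
  glucose–HbA1c r = 0.60, hemoglobin–HCT r = 0.85); total cholesterol is
  constructed as HDL-C + non-HDL-C, so the lipid identity holds exactly;
- latent liability
  `L_i = b0 + c·(x_i − x*)² + Σ_k β_k (z_ik − μ_k) + s·1[source B]`;
- deficit j is Bernoulli with probability `expit(L_i + o_j)`, with item
  offsets `o_j` equally spaced on the logit scale so item prevalences span
  ~5–60% at zero liability.

Defaults: true nadir `x* = 156.09` mg/dL; curvature `c = 1.5e-4` liability
units per (mg/dL)², chosen so the frailty odds at the far high-risk tail
(|x − x*| ≈ 108 mg/dL) are ~6× the nadir odds while the low-risk boundary
(|x − x*| ≈ 38 mg/dL) stays within ~1.25× — a pronounced but plausible U;
baseline `b0 = −0.9`, calibrated so frail prevalence is ~34% and mean FI
~0.21, matching a typical pooled 65+ cohort; source offset `s = 0.15` on
the liability scale, producing a small but nonzero between-source FI
variance (~2e-4). Randomness is split into named substreams (exposure,
covariates, items, conditions), so raising the curvature under a fixed seed
reuses the same item uniforms and deficit patterns change monotonically.
Item missingness is MCAR only.

**What the generator does not emulate.** Survey weights and design
effects; MAR/MNAR missingness; the joint covariate distribution beyond the
couplings above; and — importantly — unobserved heterogeneity: deficits are
driven entirely by the modeled liability, so fitted risk models
discriminate more strongly here (test AUC ~0.87 at the defaults) than on
real survey data, where reported AUCs for comparable models are nearer
0.71. Passing recovery tests therefore demonstrates correctness of the
estimators, not expected real-data performance.

## 3. Cohort handling

Cholesterol fields arriving in mmol/L are converted with the molar factor
38.67 (mg/dL per mmol/L), guarded by a unit flag that makes the conversion
idempotent. Eligibility: "over 65" is implemented as age ≥ 65 (the cohort
age summaries imply 65 is included); completion uses ≥ 0.75. Exclusions are
attributed to the first failing rule in the fixed order age → labs →
completion, making the log deterministic. Negative non-HDL-C (HDL above
total cholesterol, a data anomaly) is retained but flagged, with an
optional drop switch. Lifestyle columns (smoking, diet, alcohol,
self-reported hyperlipidemia) are dropped at load because they confound
the lipid exposure and are excluded from this analysis by design.

## 4. Screening cascade

The cascade order is fixed and auditable: VIF exclusion → boosted
importance ranking → low-importance categorical drop → LASSO pruning →
final set.

- **VIF**: `VIF_j = 1/(1 − R²_j)` with R² from an intercept-included OLS of
  column j on the rest; exact collinearity reports ∞. `compute_vif`
  reports every column above the threshold (the lipid identity flags all
  of TC, HDL-C and non-HDL-C). The cascade resolves collinearity
  *iteratively* — drop the highest-VIF column, recompute — with the derived
  exposure protected, so the identity resolves by discarding raw lipid
  components rather than the exposure under study. Threshold 10.
- **Boosted importance**: LightGBM with fixed hyperparameters (300 trees,
  learning rate 0.05, 31 leaves, min 20 samples/leaf, no subsampling,
  single thread) — no tuning loop anywhere. Importance is total split gain
  normalized to sum 1, ranked descending with lexicographic tie-break.
  Categorical variables below the 0.10 quantile of all importances are
  dropped (the numeric rule is a documented stand-in; no standard exists).
- **LASSO**: L1-penalized logistic regression on internally standardized
  columns, coefficients reported back on original scales. Penalty chosen
  at minimum cross-validated deviance over a 50-point log-spaced grid
  (λ ∈ [1e-4, 10], λ = 1/C) with 5 stratified folds; minimum rather than
  1-SE for determinism. λ = 0 is treated as the unpenalized ML fit.

Univariate logistic associations report OR = exp(slope) with Wald 95% CIs;
categorical predictors expand to indicator contrasts against a declared
reference within a single dummy-coded model. Zero-variance predictors are
flagged degenerate and separation is flagged non-convergent — neither
raises.

## 5. Risk models and evaluation

The train/test split is stratified by the outcome: per-class training
counts are the class sizes times the training fraction, reconciled by a
largest-remainder rule so the overall 70% target is exact and class balance
holds within one record per class. Cross-validation uses stratified
K-folds. Logistic fits are maximum likelihood with intercept; rank-deficient
designs are reduced greedily with the dropped columns named, and perfect
separation falls back to a gradient-based fit and is flagged. The ROC is a
threshold sweep over unique scores; AUC is the trapezoid integral and
equals the Mann–Whitney concordance (ties ½) to 1e-10 — the suite checks
this against a brute-force pairwise count. For a binary outcome the
micro-averaged ROC coincides with the standard ROC, so one curve is
reported.

## 6. Nonlinearity

**Partial dependence.** PD(v) is the mean predicted probability over the
cohort with the exposure forced to v on a grid of 100 points between the
1st and 99th exposure percentiles. The PD curve is a qualitative
cross-check: its argmin is required (and tested) to fall inside the derived
low-risk interval.

**Polynomial-logit fits.** The dose-response is estimated by logistic
regression with raised-power exposure terms, orders 1..4, on the
dichotomized outcome — not by fitting the PD curve, because AIC needs a
likelihood. The exposure is centered and scaled before fitting for
conditioning; coefficients are composed back to mg/dL via polynomial
substitution. `AIC = 2k − 2·log L` with `k = order + 1` (intercept
included).

**Order selection.** Among converged orders, the selected order is the
*lowest* whose AIC lies within 2 units of the minimum (exact ties likewise
go to the lower order; a tolerance of 0 recovers the strict minimum-AIC
rule). The parsimony margin is the standard "ΔAIC < 2 means equivalent
support" convention, and it matters here: strict minimum-AIC accepts an
extra polynomial order whenever that order's deviance improvement exceeds
2, which under a true lower-order model happens with asymptotic probability
P(χ²₁ > 2) ≈ 0.157 per candidate order. With two orders above the truth the
strict rule caps correct-order selection near 78%; the ΔAIC < 2 rule raises
it to ~90–94% (verified by simulation at n = 20,000) without affecting
power to detect genuine curvature.

**Nadir.** For an order-2 fit with b₂ > 0 the nadir is the vertex
−b₁/(2b₂); a concave fit or a vertex outside the observed range yields an
absent nadir with a reason. Higher orders locate interior minima on a dense
grid refined by bounded Brent minimization (robust to the repeated
derivative roots that defeat polynomial root-finding). Note a polynomial's
vertex is intrinsically flat, so location precision is limited to roughly
(machine-ε/curvature-scale)^(1/4) for quartic-dominated fits.

**Risk ranges.** The low-risk ("ideal") interval is the smallest interval
symmetric about the nadir containing ≥ 25% of the observed exposures
(half-width = the 25% quantile of |x − nadir|), so its midpoint equals the
nadir by construction. High-risk tails run from the 0.5% trim quantile to
the 12.5% quantile on the left and mirror-image on the right. The tail
construction is a documented, configurable quantile rule; published tail
bounds for comparable analyses cannot generally be reproduced as simple
marginal quantiles, so no equivalence is claimed.

## 7. Subgroups and heterogeneity

Subgroup analysis stratifies by sex, race, education and age band (65–74
vs 75+, a conventional split) and reports per-stratum adjusted exposure
odds ratios. Interaction uses a likelihood-ratio test of the exposure ×
stratifier product terms in the pooled model — chosen over Wald for
stability in small strata. Strata that are empty, single-class or smaller
than 30 records are skipped with a log entry and excluded from the LRT.
No multiple-testing correction is applied across stratifiers by default.

Between-source heterogeneity of the *continuous* FI uses a linear mixed
model with a random intercept per source; the reported quantity is the
between-group variance on the FI scale with its standard error (recovered
from the profiled parameterization by rescaling with the residual
variance) and the fixed exposure slope. Under identically generated
sources the estimate collapses toward zero (< 1e-4 in the suite's null
check).

The sensitivity refit repeats the polynomial order selection after
excluding participants flagged for heart disease, diabetes, hypertension
or stroke, reporting both selected orders and nadirs side by side.

## 8. Problem sizes and determinism

The validation suite uses n = 20,000 for asymptotic recovery checks,
n = 9,000 (20 seeds) for nadir recovery — seed-averaged mean absolute error
~0.9 mg/dL at the default curvature — and n = 1,000–10,000 elsewhere; these
sizes keep every check comfortably converged while the full suite runs in
about two minutes. All randomness flows through explicit integer seeds;
fixing the seed fixes every generated value bit-for-bit.

## 9. Known limitations

- The generator's covariates explain frailty more completely than real
  survey covariates do (Section 2), so discrimination metrics are
  optimistic relative to real data.
- MCAR missingness only; no survey weighting.
- No spline/GAM alternatives to the polynomial fits and no bootstrap CI
  for the nadir (natural extension points).
- The 40-item schema is a stand-in; real instruments differ in item
  wording and cut-points, though the FI is robust to this.
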