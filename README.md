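# frailcurve

A biostatistics pipeline for studying **U-shaped dose-response between
non-HDL cholesterol and frailty** in adults aged 65+, built around the
deficit-accumulation frailty index.

## The problem

Frailty in older adults is commonly quantified with a **frailty index (FI)**:
the fraction of health deficits present out of those assessed,

```
FI = (sum of deficit scores) / (number of items assessed),   FI ∈ [0, 1]
```

with categories non-frail (FI ≤ 0.12), pre-frail (0.12 < FI < 0.25) and
frail (FI ≥ 0.25); for dichotomous modeling the pre-frail group merges into
non-frail. Non-HDL cholesterol (non-HDL-C = total cholesterol − HDL-C,
mg/dL) aggregates all atherogenic lipoprotein cholesterol, and its relation
to frailty appears to be *nonlinear*: risk falls with rising non-HDL-C up to
a nadir and climbs again beyond it.

Detecting that U-shape rigorously requires a full chain: eligibility
filtering (age ≥ 65, ≥ 75% of FI items assessed), variable screening
(variance inflation factors, gradient-boosted importance, LASSO-penalized
logistic retention), risk modeling (multivariate logistic and LightGBM on a
stratified 70/30 split with 5-fold CV), and nonlinearity analysis: partial
dependence, logistic fits with polynomial exposure terms selected by AIC
(`AIC = 2k − 2·log L`), the nadir of the order-2 fit (`x* = −b₁ / 2b₂`),
and quartile-based risk ranges around it. `frailcurve` implements every
stage as a tested library plus a thin CLI, driven by a **synthetic cohort
generator with a known, configurable U-shaped ground truth**, so each stage
can be validated by parameter recovery instead of by eyeballing.

## Worked example

```bash
frailcurve simulate --n 9000 --seed 1 --out demo.csv
frailcurve build-cohort --in demo.csv --out cohort.csv --log excl.tsv
frailcurve build-fi --in cohort.csv --out scored.csv
frailcurve screen --in scored.csv --seed 1 --out screen_out
frailcurve fit --in scored.csv --vars-from screen_out/screening.json --seed 1 --out model.json
frailcurve nonlinear --in scored.csv --out nl_out
frailcurve subgroup --in scored.csv --out sg_out
```

prints

```
wrote 9000 participants to demo.csv
retained 9000/9000; exclusions: {'age': 0, 'labs': 0, 'completion': 0}
mean FI 0.206; frail fraction 0.334
VIF-excluded: ['total_cholesterol']; final set: ['age', 'hdl_c', 'non_hdl_c', ...]
test AUC 0.872; CV fold AUCs [0.875 0.866 0.873 0.886 0.883]
selected order 2; nadir 155.42 mg/dL; ideal range 141.55-169.29
group variance 2.42e-04
wrote 12 subgroup rows to sg_out
```

Reading the output: the generated cohort has ~33% frail prevalence and its
deficit liability is quadratic in non-HDL-C with a true nadir at
156.09 mg/dL. The screen drops total cholesterol (infinite VIF against the
exact identity TC = HDL + non-HDL) while protecting the derived exposure;
the AIC comparison of polynomial orders 1–4 picks the quadratic; the fitted
vertex (155.42 mg/dL) recovers the generating nadir to under 1 mg/dL; the
"ideal range" is the smallest interval symmetric about the nadir holding
25% of the exposure mass. The between-source variance of the FI from the
random-intercept mixed model (2.4e-4) quantifies how little of the FI
variation is attributable to which survey a participant came from.

The same pipeline is importable as a library
(`frailcurve.generate_cohort`, `add_fi_columns`, `run_screening`,
`fit_polynomial_logit`, `find_nadir`, `derive_risk_ranges`, ...); see
`docs/methods.md` for the statistical details and design choices.

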