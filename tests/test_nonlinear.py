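"""Partial dependence, polynomial-logit AIC selection, nadir, risk ranges."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from frailcurve import (
    PolyFit,
    SimulationParams,
    add_fi_columns,
    default_grid,
    derive_risk_ranges,
    find_nadir,
    fit_polynomial_logit,
    generate_cohort,
    partial_dependence,
)
from frailcurve.modeling import ModelBundle


def _manual_bundle(fn, variables):
    return ModelBundle("logistic", variables, predict=lambda df: np.asarray(fn(df), dtype=float))


class TestPartialDependence:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.cohort = pd.DataFrame({"x": rng.normal(150, 30, 500),
                                    "z": rng.normal(0, 1, 500)})

    def test_model_ignoring_feature_gives_flat_pd(self):
        bundle = _manual_bundle(lambda df: np.full(len(df), 0.3), ["x", "z"])
        curve = partial_dependence(bundle, "x", np.linspace(100, 200, 50), self.cohort)
        assert curve.pd_values.max() - curve.pd_values.min() < 1e-9

    def test_quadratic_model_pd_argmin_at_analytic_vertex(self):
        vertex = 150.0
        bundle = _manual_bundle(
            lambda df: expit(-1.0 + 4e-4 * (df["x"] - vertex) ** 2 + 0.5 * df["z"]),
            ["x", "z"])
        grid = np.linspace(100, 200, 101)  # step 1 mg/dL
        curve = partial_dependence(bundle, "x", grid, self.cohort)
        assert abs(curve.argmin() - vertex) <= 1.0

    def test_single_point_grid_is_mean_prediction(self):
        bundle = _manual_bundle(lambda df: expit(0.01 * df["x"] + df["z"]), ["x", "z"])
        curve = partial_dependence(bundle, "x", [140.0], self.cohort)
        forced = self.cohort.assign(x=140.0)
        assert curve.pd_values[0] == pytest.approx(float(np.mean(bundle.predict(forced))))

    def test_pd_of_additive_logistic_recovers_univariate_response(self):
        """With every other covariate at a common value, PD reproduces the
        model's own response curve exactly (no interactions to average)."""
        bundle = _manual_bundle(lambda df: expit(-0.5 + 0.02 * df["x"] + 0.0 * df["z"]),
                                ["x", "z"])
        grid = np.linspace(100, 200, 100)
        curve = partial_dependence(bundle, "x", grid, self.cohort)
        assert np.max(np.abs(curve.pd_values - expit(-0.5 + 0.02 * grid))) < 1e-6

    def test_errors(self):
        bundle = _manual_bundle(lambda df: np.full(len(df), 0.5), ["z"])
        with pytest.raises(KeyError):
            partial_dependence(bundle, "x", [1.0], self.cohort)
        bundle2 = _manual_bundle(lambda df: np.full(len(df), 0.5), ["x"])
        with pytest.raises(ValueError):
            partial_dependence(bundle2, "x", [], self.cohort)

    def test_default_grid_spans_inner_percentiles(self):
        x = np.random.default_rng(1).normal(135, 37, 5000)
        g = default_grid(x)
        assert len(g) == 100
        assert g[0] == pytest.approx(np.percentile(x, 1))
        assert g[-1] == pytest.approx(np.percentile(x, 99))


def _simulate_logit(n, seed, fn):
    rng = np.random.default_rng(seed)
    x = np.clip(rng.normal(134.9, 36.7, n), 40, 320)
    y = (rng.random(n) < expit(fn(x))).astype(int)
    return y, x


class TestPolynomialLogit:
    def test_aic_is_definitional(self):
        y, x = _simulate_logit(3000, 0, lambda x: -0.5 + 0.01 * (x - 135))
        fits, _ = fit_polynomial_logit(y, x, max_order=3)
        for fit in fits:
            assert fit.aic == pytest.approx(2 * (fit.order + 1) - 2 * fit.log_likelihood)

    def test_linear_truth_selects_order_one(self):
        y, x = _simulate_logit(20000, 1, lambda x: -0.6 + 0.01 * (x - 134.9))
        _, sel = fit_polynomial_logit(y, x)
        assert sel.order == 1

    def test_quadratic_truth_selects_order_two_and_recovers_vertex(self):
        y, x = _simulate_logit(20000, 2, lambda x: -1.2 + 1.5e-4 * (x - 156.09) ** 2)
        _, sel = fit_polynomial_logit(y, x)
        assert sel.order == 2
        nadir = find_nadir(sel, (x.min(), x.max()))
        assert abs(nadir.value - 156.09) < 5.0

    def test_coefficients_reported_on_original_scale(self):
        y, x = _simulate_logit(20000, 3, lambda x: -1.2 + 1.5e-4 * (x - 156.09) ** 2)
        fits, _ = fit_polynomial_logit(y, x, max_order=2)
        fit2 = fits[1]
        # evaluate the back-transformed polynomial against the truth shape
        grid = np.linspace(60, 280, 20)
        truth = -1.2 + 1.5e-4 * (grid - 156.09) ** 2
        assert np.max(np.abs(fit2.logit_at(grid) - truth)) < 0.25

    def test_bad_max_order(self):
        with pytest.raises(ValueError):
            fit_polynomial_logit([0, 1], [1.0, 2.0], max_order=0)


class TestFindNadir:
    def test_vertex_identity(self):
        # logit(p) = 1 + 0.0004 (x - 150)^2, expanded into b0, b1, b2
        fit = PolyFit(2, np.array([1 + 0.0004 * 150**2, -0.0004 * 300, 0.0004]), 0.0, 0.0)
        res = find_nadir(fit, (40.0, 320.0))
        assert res.value == pytest.approx(150.0)

    def test_concave_fit_has_no_nadir(self):
        fit = PolyFit(2, np.array([0.0, 0.03, -1e-4]), 0.0, 0.0)
        res = find_nadir(fit, (40.0, 320.0))
        assert res.value is None and "concave" in res.reason

    def test_vertex_outside_range_reported_absent(self):
        fit = PolyFit(2, np.array([1 + 0.0004 * 500**2, -0.0004 * 1000, 0.0004]), 0.0, 0.0)
        res = find_nadir(fit, (40.0, 320.0))
        assert res.value is None and "outside" in res.reason

    def test_quartic_interior_minimum(self):
        # (x-150)^4-like bowl: minimum at 150
        from numpy.polynomial import Polynomial
        p = Polynomial([0.0]) + 1e-8 * Polynomial([-150.0, 1.0]) ** 4
        coefs = np.zeros(5)
        coefs[: len(p.coef)] = p.coef
        # a quartic is extremely flat at its vertex, so numerical location is
        # only conditioned to ~(eps/scale)^(1/4); 0.1 mg/dL is ample here
        res = find_nadir(PolyFit(4, coefs, 0.0, 0.0), (40.0, 320.0))
        assert res.value == pytest.approx(150.0, abs=0.1)

    def test_order_one_has_no_curvature(self):
        res = find_nadir(PolyFit(1, np.array([0.0, 0.01]), 0.0, 0.0), (40.0, 320.0))
        assert res.value is None


class TestRiskRanges:
    def test_uniform_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 100, 100000)
        rr = derive_risk_ranges(x, nadir=50.0)
        assert rr.ideal[0] == pytest.approx(37.5, abs=0.5)
        assert rr.ideal[1] == pytest.approx(62.5, abs=0.5)
        assert rr.low_tail[1] == pytest.approx(12.5, abs=0.5)
        assert rr.high_tail[0] == pytest.approx(87.5, abs=0.5)

    def test_ideal_midpoint_is_the_nadir(self):
        rng = np.random.default_rng(5)
        x = rng.normal(135, 37, 5000)
        nadir = 156.09
        rr = derive_risk_ranges(x, nadir)
        assert (rr.ideal[0] + rr.ideal[1]) / 2 == pytest.approx(nadir, abs=1e-9)

    def test_zero_central_mass_degenerates(self):
        x = np.random.default_rng(6).uniform(0, 100, 1000)
        rr = derive_risk_ranges(x, 50.0, central_mass=0.0)
        assert rr.degenerate and rr.ideal == (50.0, 50.0)

    def test_intervals_disjoint_and_ordered(self):
        rng = np.random.default_rng(7)
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(150, 40, 2000)
            nadir = float(np.quantile(x, r.uniform(0.3, 0.7)))
            rr = derive_risk_ranges(x, nadir)
            assert rr.low_tail[0] <= rr.low_tail[1] < rr.ideal[0] < rr.ideal[1] \
                < rr.high_tail[0] <= rr.high_tail[1]

    def test_errors(self):
        x = np.random.default_rng(8).uniform(0, 100, 1000)
        with pytest.raises(ValueError, match="outside"):
            derive_risk_ranges(x, 150.0)
        with pytest.raises(ValueError, match="masses"):
            derive_risk_ranges(x, 50.0, central_mass=0.9, tail_mass=0.2)


def test_nadir_recovery_error_shrinks_with_sample_size():
    """Seed-averaged absolute nadir-recovery error decreases monotonically
    over n in {1000, 4000, 9000} on default cohorts (order-2 fit)."""
    def mae(n):
        errs = []
        for seed in range(10):
            df, _ = generate_cohort(SimulationParams(n_participants=n, seed=seed))
            sc = add_fi_columns(df)
            fits, _ = fit_polynomial_logit(sc["frail_binary"].astype(int),
                                           sc["non_hdl_c"], max_order=2)
            nad = find_nadir(fits[1], (sc["non_hdl_c"].min(), sc["non_hdl_c"].max()))
            errs.append(abs(nad.value - 156.09) if nad.value is not None else 50.0)
        return float(np.mean(errs))

    m1000, m4000, m9000 = mae(1000), mae(4000), mae(9000)
    assert m9000 < m4000 < m1000


def test_pdp_argmin_falls_in_the_derived_ideal_range(large_cohort):
    """Qualitative cross-check: the partial-dependence valley of the boosted
    model lies inside the quartile-based low-risk interval."""
    from frailcurve import fit_boosted

    df = large_cohort[0].dropna(subset=["frail_binary"]).reset_index(drop=True)
    variables = ["age", "non_hdl_c", "glucose", "creatinine", "wbc", "hemoglobin",
                 "hba1c", "bmi", "waist"]
    booster = fit_boosted(df, variables, "frail_binary", seed=0)
    curve = partial_dependence(booster, "non_hdl_c", default_grid(df["non_hdl_c"]), df)
    fits, sel = fit_polynomial_logit(df["frail_binary"].astype(int), df["non_hdl_c"])
    nad = find_nadir(sel, (df["non_hdl_c"].min(), df["non_hdl_c"].max()))
    rr = derive_risk_ranges(df["non_hdl_c"], nad.value)
    assert rr.ideal[0] <= curve.argmin() <= rr.ideal[1]
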