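"""Logistic MLE, sandwich covariance, and the model hierarchy."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from selectqba.models import (
    Z_95,
    fit_logistic,
    robust_covariance,
    run_hierarchy,
)
from selectqba.synth import ExposureSpec, SimulationConfig, simulate_study


def two_by_two(a, b, c, d):
    """Rows for a saturated 2x2: exposed cases a, exposed controls b,
    unexposed cases c, unexposed controls d."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return np.column_stack([np.ones_like(x), x]), y


def small_fixture(n=30, seed=7):
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [np.ones(n), rng.normal(size=n), rng.integers(0, 2, n).astype(float)]
    )
    beta = np.array([0.2, 0.5, -0.3])
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-X @ beta))).astype(float)
    return X, y


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product_ratio(self):
        a, b, c, d = 291, 27, 3571, 1526
        X, y = two_by_two(a, b, c, d)
        fit = fit_logistic(X, y)
        assert np.exp(fit.params[1]) == pytest.approx(a * d / (b * c), abs=1e-6)
        assert fit.converged

    def test_all_zero_column_errors(self):
        X, y = two_by_two(5, 5, 5, 5)
        X = np.column_stack([X, np.zeros(len(y))])
        with pytest.raises(ValueError, match="constant-zero"):
            fit_logistic(X, y)

    def test_single_class_outcome_errors(self):
        X, _ = two_by_two(5, 5, 5, 5)
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(X, np.ones(20))

    def test_rank_deficient_design_names_columns(self):
        X, y = small_fixture()
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(X, y, colnames=["const", "a", "b", "a_copy"])

    def test_null_recovery(self):
        """Outcome independent of exposure: OR near 1, CI covers 1."""
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        fit = fit_logistic(
            np.column_stack([np.ones(n), x]), y, colnames=["const", "x"]
        )
        res = fit.or_result("x")
        assert res.ci_low < 1.0 < res.ci_high

    def test_separation_flagged_not_raised(self):
        # perfect separation on x
        n = 40
        x = np.concatenate([np.ones(20), np.zeros(20)])
        y = x.copy()
        X = np.column_stack([np.ones(n), x])
        fit = fit_logistic(X, y)
        assert fit.separated[1] or not fit.converged
        assert not fit.or_result("x1").estimable

    def test_row_order_invariance(self):
        X, y = small_fixture()
        fit1 = fit_logistic(X, y)
        perm = np.random.default_rng(3).permutation(len(y))
        fit2 = fit_logistic(X[perm], y[perm])
        np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-8)
        np.testing.assert_allclose(fit1.cov_robust, fit2.cov_robust, atol=1e-8)

    def test_affine_rescaling_equivariance(self):
        """Rescaling a continuous column scales its coefficient inversely;
        shifts are absorbed by the intercept."""
        X, y = small_fixture(n=200, seed=2)
        fit1 = fit_logistic(X, y)
        X2 = X.copy()
        X2[:, 1] = 10.0 * X[:, 1] + 5.0
        fit2 = fit_logistic(X2, y)
        assert fit2.params[1] == pytest.approx(fit1.params[1] / 10.0, rel=1e-6)


class TestRobustCovariance:
    def test_matches_brute_force_scores(self):
        """Sandwich from analytic scores agrees with a finite-difference
        per-observation score computation to 1e-6."""
        X, y = small_fixture()
        params = fit_logistic(X, y).params
        eps = 1e-6
        n, k = X.shape

        def ll_obs(b):
            p = 1.0 / (1.0 + np.exp(-X @ b))
            return y * np.log(p) + (1 - y) * np.log(1 - p)

        scores = np.zeros((n, k))
        for j in range(k):
            up, dn = params.copy(), params.copy()
            up[j] += eps
            dn[j] -= eps
            scores[:, j] = (ll_obs(up) - ll_obs(dn)) / (2 * eps)
        p = 1.0 / (1.0 + np.exp(-X @ params))
        bread = X.T @ (X * (p * (1 - p))[:, None])
        oracle = np.linalg.inv(bread) @ scores.T @ scores @ np.linalg.inv(bread)
        oracle *= n / (n - k)
        np.testing.assert_allclose(
            robust_covariance(X, y, params), oracle, atol=1e-6
        )

    def test_matches_statsmodels_sandwich(self):
        """HC0 flavor equals the statsmodels Logit robust covariance."""
        X, y = small_fixture(n=120, seed=9)
        res = sm.Logit(y, X).fit(disp=0)
        mine = robust_covariance(X, y, np.asarray(res.params), small_sample="HC0")
        theirs = sm.Logit(y, X).fit(disp=0, cov_type="HC1").cov_params()
        np.testing.assert_allclose(mine, np.asarray(theirs), atol=1e-8)

    def test_saturated_2x2_equals_woolf_up_to_hc1(self):
        a, b, c, d = 291, 27, 3571, 1526
        X, y = two_by_two(a, b, c, d)
        fit = fit_logistic(X, y)
        woolf = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        n = len(y)
        se = np.sqrt(fit.cov_robust[1, 1])
        assert se == pytest.approx(woolf * np.sqrt(n / (n - 2)), abs=1e-9)

    def test_duplicating_rows_shrinks_se(self):
        X, y = small_fixture(n=200, seed=4)
        params = fit_logistic(X, y).params
        cov1 = robust_covariance(X, y, params, small_sample="HC0")
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        cov2 = robust_covariance(X2, y2, params, small_sample="HC0")
        np.testing.assert_allclose(np.diag(cov2), np.diag(cov1) / 2, rtol=1e-8)

    def test_wald_ci_invariant(self):
        X, y = small_fixture(n=100, seed=5)
        fit = fit_logistic(X, y, colnames=["const", "a", "b"])
        for term in ("a", "b"):
            r = fit.or_result(term)
            assert r.ci_low < r.or_estimate < r.ci_high
            assert r.ci_low == pytest.approx(
                np.exp(np.log(r.or_estimate) - Z_95 * r.se_ln_or), abs=1e-9
            )
            assert r.ci_high == pytest.approx(
                np.exp(np.log(r.or_estimate) + Z_95 * r.se_ln_or), abs=1e-9
            )


@pytest.fixture(scope="module")
def study():
    cfg = SimulationConfig(
        n_cases=10_000,
        n_controls_target=10_000,
        control_pool_multiplier=1.0,
        exposure_specs=[
            ExposureSpec("mental illness", 0.10, 2.0),
            ExposureSpec("pain", 0.08, 1.5),
        ],
        noise_visit_rate=0.0,
        seed=21,
    )
    cohort = simulate_study(cfg)
    persons = cohort.persons.copy()
    persons["status"] = np.where(
        persons["person_id"].str.startswith("case-"), "case", "control"
    )
    return persons, cohort.exposures


class TestHierarchy:
    def test_parameter_recovery_within_ci(self, study):
        """With no confounding or selection, the adjusted OR's 95% CI covers
        the generating odds ratio."""
        persons, expo = study
        res = run_hierarchy(persons, expo, variant="separate")
        row = res[res["term"] == "mental illness"].iloc[0]
        assert row["ci_low"] < 2.0 < row["ci_high"]
        row = res[res["term"] == "pain"].iloc[0]
        assert row["ci_low"] < 1.5 < row["ci_high"]

    def test_separate_vs_simultaneous_agree_when_independent(self, study):
        persons, expo = study
        sep = run_hierarchy(persons, expo, variant="separate")
        sim = run_hierarchy(persons, expo, variant="simultaneous")
        for term in ("mental illness", "pain"):
            b1 = np.log(sep.loc[sep["term"] == term, "or_estimate"].iloc[0])
            b2 = np.log(sim.loc[sim["term"] == term, "or_estimate"].iloc[0])
            se = sep.loc[sep["term"] == term, "se_ln_or"].iloc[0]
            assert abs(b1 - b2) < 3 * se

    def test_single_term_simultaneous_equals_separate(self, study):
        persons, expo = study
        sep = run_hierarchy(persons, expo, variant="separate", terms=["pain"])
        sim = run_hierarchy(persons, expo, variant="simultaneous", terms=["pain"])
        assert sep["or_estimate"].iloc[0] == pytest.approx(
            sim["or_estimate"].iloc[0], abs=1e-10
        )

    def test_components_variant_runs_both_levels(self, small_cohort):
        from selectqba.exposures import code_exposures

        _, cohort = small_cohort
        persons = cohort.persons.copy()
        persons["status"] = np.where(
            persons["person_id"].str.startswith("case-"), "case", "control"
        )
        matrix = code_exposures(persons, cohort.visits)
        res = run_hierarchy(persons, matrix, variant="components")
        assert set(res["variant"]) == {"separate", "simultaneous"}
        # non-estimable terms are reported, never dropped
        assert res["term"].notna().all()
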