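"""FIML likelihood, optimization, standard errors and derived quantities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riclpm.estimation import (
    FitOptions,
    em_saturated,
    fiml_loglik,
    fit,
    icc,
    missingness_patterns,
    predictor_effects,
    ri_variance_explained,
    standard_errors,
)
from riclpm.model import ModelConfig, build_model, implied_moments
from riclpm.simulate import simulate_cohort, true_theta


def _just_identified_spec():
    """K=1, T=3 free model: 9 parameters against 9 saturated moments."""
    return build_model(ModelConfig(1, 3, scheme="free"))


def _complete_data(n=400, seed=0, p=3, rho=0.45):
    rng = np.random.default_rng(seed)
    cov = rho * np.ones((p, p)) + (1 - rho) * np.eye(p)
    return rng.multivariate_normal(np.arange(p, dtype=float), cov, size=n)


class TestMissingnessPatterns:
    def test_complete_data_single_pattern(self):
        patterns, n, dropped = missingness_patterns(_complete_data(50))
        assert len(patterns) == 1 and n == 50 and dropped == 0
        assert patterns[0].count == 50

    def test_two_masks(self):
        X = _complete_data(40)
        X[:15, 2] = np.nan
        patterns, n, _ = missingness_patterns(X)
        assert len(patterns) == 2
        assert sorted(p.count for p in patterns) == [15, 25]
        assert n == 40

    def test_all_missing_rows_dropped_with_warning(self):
        X = _complete_data(10)
        X[3] = np.nan
        with pytest.warns(UserWarning, match="no observed"):
            _, n, dropped = missingness_patterns(X)
        assert n == 9 and dropped == 1

    def test_bernoulli_dropout_marginals(self):
        rng = np.random.default_rng(42)
        n, p_miss = 20_000, 0.3
        X = rng.normal(size=(n, 2))
        X[rng.random(n) < p_miss, 1] = np.nan
        patterns, n_used, _ = missingness_patterns(X)
        miss = sum(p.count for p in patterns if not p.mask[1]) / n_used
        assert abs(miss - p_miss) < 3 / np.sqrt(n)


class TestFimlLoglik:
    def test_standard_normal_point_density(self):
        # one fully observed subject at the mean with identity covariance
        spec = _just_identified_spec()
        theta = spec.start_vector()
        theta[spec.mean_idx[0]] = [0.0, 0.0, 0.0]
        theta[spec.psi_idx[0, 0]] = 0.0
        theta[spec.sw1_idx[0, 0]] = 1.0
        theta[spec.theta_idx[:, 0, 0]] = 1.0
        theta[spec.B_idx[:, 0, 0]] = 0.0
        patterns, _, _ = missingness_patterns(np.zeros((1, 3)))
        assert fiml_loglik(spec, theta, patterns) == pytest.approx(-1.5 * np.log(2 * np.pi))

    def test_complete_data_closed_form(self):
        # no missingness: ll equals the closed-form MVN expression with the
        # divide-by-N covariance
        spec = _just_identified_spec()
        X = _complete_data(200, seed=1)
        patterns, n, _ = missingness_patterns(X)
        theta = spec.start_vector()
        theta[spec.mean_idx[0]] = [0.1, 0.9, 2.2]
        theta[spec.psi_idx[0, 0]] = 0.4
        theta[spec.sw1_idx[0, 0]] = 0.7
        theta[spec.theta_idx[:, 0, 0]] = 0.6
        theta[spec.B_idx[:, 0, 0]] = 0.2
        mu, Sigma = implied_moments(spec, theta)
        xbar = X.mean(0)
        S = np.cov(X.T, ddof=0)
        Sinv = np.linalg.inv(Sigma)
        d = xbar - mu
        closed = -0.5 * n * (
            3 * np.log(2 * np.pi)
            + np.linalg.slogdet(Sigma)[1]
            + np.trace(S @ Sinv)
            + d @ Sinv @ d
        )
        assert fiml_loglik(spec, theta, patterns) == pytest.approx(closed, rel=1e-10)

    def test_patterned_data_matches_per_row_oracle(self):
        # brute force: sum of each row's marginal normal log-density over its
        # observed entries
        spec = build_model(ModelConfig(1, 2, scheme="free"))
        theta = spec.start_vector()
        theta[spec.mean_idx[0]] = [0.5, -0.5]
        theta[spec.psi_idx[0, 0]] = 0.3
        theta[spec.sw1_idx[0, 0]] = 0.8
        theta[spec.theta_idx[0, 0, 0]] = 0.5
        theta[spec.B_idx[0, 0, 0]] = 0.4
        mu, Sigma = implied_moments(spec, theta)
        X = np.array([[1.0, 2.0], [0.0, np.nan], [np.nan, -1.0], [0.3, 0.4], [2.0, np.nan]])
        oracle = 0.0
        for row in X:
            o = ~np.isnan(row)
            oracle += stats.multivariate_normal.logpdf(
                row[o], mu[o], Sigma[np.ix_(o, o)], allow_singular=False
            )
        patterns, _, _ = missingness_patterns(X)
        assert fiml_loglik(spec, theta, patterns) == pytest.approx(oracle, rel=1e-10)

    def test_singular_subblock_named(self):
        spec = build_model(ModelConfig(1, 2, scheme="free"))
        theta = spec.start_vector()  # all variances at tiny defaults are fine
        theta[spec.psi_idx[0, 0]] = 0.0
        theta[spec.sw1_idx[0, 0]] = 0.0
        theta[spec.theta_idx[0, 0, 0]] = 1.0
        patterns, _, _ = missingness_patterns(np.array([[0.0, 0.0]]))
        with pytest.raises(np.linalg.LinAlgError, match="pattern"):
            fiml_loglik(spec, theta, patterns)


class TestEmSaturated:
    def test_complete_data_closed_form_ml(self):
        X = _complete_data(300, seed=2)
        patterns, n, _ = missingness_patterns(X)
        mu, Sigma, ll, _ = em_saturated(patterns, 3)
        assert np.allclose(mu, X.mean(0), atol=1e-6)
        assert np.allclose(Sigma, np.cov(X.T, ddof=0), atol=1e-6)

    def test_attrition_patterns_converge(self, reduced_cohort):
        # EM on the cohort's wave-wise attrition patterns reaches a finite
        # optimum well inside the iteration budget
        panel = reduced_cohort.panel[[c for c in reduced_cohort.panel.columns
                                      if c.endswith(("_t1", "_t2", "_t3", "_t4")) or c == "pgi"]]
        patterns, _, _ = missingness_patterns(panel)
        _, Sigma, ll, n_iter = em_saturated(patterns, panel.shape[1])
        assert np.isfinite(ll) and n_iter < 2000
        assert np.linalg.eigvalsh(Sigma)[0] > 0


class TestFit:
    def test_just_identified_model_reproduces_sample_moments(self):
        # with q equal to the saturated moment count, the fitted implied
        # moments equal the sample mean and ML covariance
        spec = _just_identified_spec()
        X = _complete_data(500, seed=3)
        res = fit(spec, X, options=FitOptions(compute_se=False))
        mu, Sigma = res.implied_moments()
        assert np.allclose(mu, X.mean(0), atol=1e-5)
        assert np.allclose(Sigma, np.cov(X.T, ddof=0), atol=1e-5)

    def test_parameter_recovery_single_replicate(self, reduced_params, reduced_scheme_fits):
        spec = build_model(reduced_params.model_config(scheme="free"))
        theta_true = true_theta(reduced_params, spec)
        res = reduced_scheme_fits["free"]
        z = np.abs(res.theta - theta_true) / res.se
        # a single replicate: all parameters within 4 SE, most within 2
        assert z.max() < 4.0
        assert (z < 2.0).mean() > 0.8

    def test_likelihood_monotone_in_nesting(self, reduced_scheme_fits):
        lls = [reduced_scheme_fits[s].loglik for s in ("constrained", "first_free", "free")]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_permutation_invariance(self, reduced_params, reduced_cohort, reduced_scheme_fits):
        spec = build_model(reduced_params.model_config(scheme="free"))
        shuffled = reduced_cohort.panel.sample(frac=1.0, random_state=7).reset_index(drop=True)
        res = fit(spec, shuffled, options=FitOptions(compute_se=False))
        assert np.allclose(res.theta, reduced_scheme_fits["free"].theta, atol=1e-6)

    def test_seeded_determinism(self, reduced_params, reduced_cohort):
        spec = build_model(reduced_params.model_config(scheme="constrained"))
        opts = FitOptions(compute_se=False, seed=5)
        a = fit(spec, reduced_cohort.panel, options=opts)
        b = fit(spec, reduced_cohort.panel, options=opts)
        assert np.array_equal(a.theta, b.theta)
        assert a.loglik == b.loglik

    def test_compound_symmetry_icc_recovery(self):
        # RI var 0.6, within var 0.4, zero paths -> ICC -> 0.6
        rng = np.random.default_rng(8)
        n = 20_000
        ri = rng.normal(0, np.sqrt(0.6), size=n)
        X = ri[:, None] + rng.normal(0, np.sqrt(0.4), size=(n, 4))
        spec = build_model(ModelConfig(1, 4, scheme="constrained"))
        res = fit(spec, X, options=FitOptions(compute_se=False))
        assert icc(res)[0] == pytest.approx(0.6, abs=0.02)
        assert np.allclose(ri_variance_explained(res), 0.6, atol=0.02)

    def test_zero_ri_variance_gives_zero_icc(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(4000, 3))  # independent waves, no stable component
        spec = build_model(ModelConfig(1, 3, scheme="free"))
        res = fit(spec, X, options=FitOptions(compute_se=False))
        assert icc(res)[0] == pytest.approx(0.0, abs=0.02)


class TestStandardErrors:
    def test_mean_se_closed_form(self):
        # just-identified model: SE of a mean parameter is sigma_hat/sqrt(n)
        spec = _just_identified_spec()
        X = _complete_data(2000, seed=4)
        res = fit(spec, X)
        sd = X.std(0, ddof=0)
        for t in range(3):
            j = spec.mean_idx[0, t]
            assert res.se[j] == pytest.approx(sd[t] / np.sqrt(len(X)), rel=1e-4)

    def test_duplicated_data_halves_variance(self):
        spec = _just_identified_spec()
        X = _complete_data(300, seed=5)
        res1 = fit(spec, X)
        res2 = fit(spec, np.vstack([X, X]))
        assert np.allclose(res2.se, res1.se / np.sqrt(2), rtol=1e-3)

    def test_sandwich_close_to_observed_under_normality(self):
        spec = _just_identified_spec()
        X = _complete_data(100_000, seed=6)
        res = fit(spec, X, options=FitOptions(compute_se=False))
        so = standard_errors(res, method="observed_information")
        ss = standard_errors(res, method="sandwich")
        assert np.all(ss / so > 0.9) and np.all(ss / so < 1.1)


@pytest.fixture(scope="module")
def predictor_fit(reduced_params, reduced_cohort):
    spec = build_model(reduced_params.model_config(scheme="free"))
    return fit(spec, reduced_cohort.panel)


class TestPredictorEffects:
    def test_beta_recovers_generator_target(self, predictor_fit, reduced_params):
        # generator targets standardized betas (0.09, -0.18) for the subset
        beta = predictor_effects(predictor_fit)["beta_std"]
        assert beta[0] == pytest.approx(0.09, abs=0.05)
        assert beta[1] == pytest.approx(-0.18, abs=0.05)

    def test_variance_share_identity(self, predictor_fit):
        # share of indicator variance = beta_std^2 * RI R^2, exactly on the
        # implied moments
        eff = predictor_effects(predictor_fit)
        r2 = ri_variance_explained(predictor_fit)
        expected = (eff["beta_std"] ** 2)[:, None] * r2
        assert np.allclose(eff["variance_share"], expected, atol=1e-10)

    def test_absent_predictor_raises(self):
        spec = build_model(ModelConfig(1, 3, scheme="free"))
        X = _complete_data(200, seed=9)
        res = fit(spec, X, options=FitOptions(compute_se=False))
        with pytest.raises(ValueError, match="predictor"):
            predictor_effects(res)
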