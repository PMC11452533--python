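"""Model specification: parameter bookkeeping, implied moments, standardization."""

import numpy as np
import pytest

from riclpm.model import (
    ModelConfig,
    ModelSpec,
    build_model,
    count_free_parameters,
    implied_moments,
    standardize,
)
from riclpm.simulate import TrueParameters, simulate_cohort, true_theta


def _count(scheme="free", means="free", predictor="none", K=4, T=4):
    return count_free_parameters(
        build_model(ModelConfig(K, T, scheme=scheme, means=means, predictor=predictor))
    )


class TestParameterCounts:
    def test_full_design_with_predictor(self):
        # 16 means + 2 predictor moments + 4 regressions + 10 RI covariances
        # + 10 wave-1 covariances + 48 transitions + 30 residual covariances
        assert _count(predictor="on_random_intercepts") == 120

    def test_scheme_differences_match_nested_test_dfs(self):
        assert _count("free") - _count("constrained") == 32
        assert _count("free") - _count("first_free") == 16

    def test_grand_mean_constraint_removes_kx_tminus1(self):
        assert _count(means="free") - _count(means="equal_over_waves") == 12

    def test_minimal_design_hand_enumeration(self):
        # K=1, T=2: 2 means + RI var + wave-1 var + 1 AR + 1 residual var
        assert _count(K=1, T=2) == 6

    def test_predictor_on_observed_counts(self):
        # on_observed replaces K RI regressions with K*T direct paths
        assert _count(predictor="on_observed") == 120 - 4 + 16

    def test_nesting_is_a_refinement(self):
        # every parameter of a more restricted scheme maps onto the freer one
        assert _count("constrained") < _count("first_free") < _count("free")

    def test_first_free_requires_three_waves(self):
        with pytest.raises(ValueError, match="at least 3 waves"):
            build_model(ModelConfig(2, 2, scheme="first_free"))


def _theta_by_label(spec, **values):
    theta = np.zeros(spec.n_free)
    labels = list(spec.params["label"])
    for label, value in values.items():
        theta[labels.index(label)] = value
    return theta


class TestImpliedMoments:
    def test_compound_symmetry(self):
        # one construct, zero paths, RI var 0.6 and within var 0.4 at every
        # wave: unit diagonal with all off-diagonals equal to the RI variance
        spec = build_model(ModelConfig(1, 4, scheme="free"))
        theta = _theta_by_label(
            spec, psi_c1=0.6, sw1_c1=0.4, theta_t2_c1=0.4, theta_t3_c1=0.4, theta_t4_c1=0.4
        )
        _, Sigma = implied_moments(spec, theta)
        assert np.allclose(np.diag(Sigma), 1.0)
        off = Sigma[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.6)

    def test_propagation_through_one_transition(self):
        # no RI: w2 = 0.5 w1 + e2 with var(w1)=1, var(e2)=0.75
        spec = build_model(ModelConfig(1, 2, scheme="free"))
        theta = _theta_by_label(spec, sw1_c1=1.0, theta_t2_c1=0.75)
        theta[list(spec.params["label"]).index("beta_t2_c1~c1")] = 0.5
        _, Sigma = implied_moments(spec, theta)
        assert Sigma[0, 1] == pytest.approx(0.5)
        assert Sigma[1, 1] == pytest.approx(0.5**2 * 1.0 + 0.75)

    def test_predictor_covariance_constant_over_waves(self):
        # cov(g, x_{k,t}) = b_k var_g for every wave t
        spec = build_model(ModelConfig(2, 3, scheme="free", predictor="on_random_intercepts"))
        theta = spec.start_vector()
        labels = list(spec.params["label"])
        theta[labels.index("var_g")] = 2.0
        theta[labels.index("b_c1")] = 0.3
        theta[labels.index("b_c2")] = -0.2
        for lab in labels:
            if lab.startswith(("psi_c", "sw1_c", "theta_")) and "." not in lab:
                theta[labels.index(lab)] = 0.5
        _, Sigma = implied_moments(spec, theta)
        g = spec.n_observed - 1
        assert np.allclose(Sigma[g, 0:3], 0.3 * 2.0)
        assert np.allclose(Sigma[g, 3:6], -0.2 * 2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_implied_covariance_psd_for_admissible_draws(self, seed):
        rng = np.random.default_rng(seed)
        K, T = 3, 4
        spec = build_model(ModelConfig(K, T, scheme="free", predictor="on_random_intercepts"))
        theta = spec.start_vector()

        def rand_psd(k):
            A = rng.normal(size=(k, k)) * 0.5
            return A @ A.T + 0.1 * np.eye(k)

        Psi, Sw1 = rand_psd(K), rand_psd(K)
        for k in range(K):
            for l in range(k, K):
                theta[spec.psi_idx[k, l]] = Psi[k, l]
                theta[spec.sw1_idx[k, l]] = Sw1[k, l]
        for t in range(T - 1):
            Th = rand_psd(K)
            for k in range(K):
                for l in range(k, K):
                    theta[spec.theta_idx[t, k, l]] = Th[k, l]
            for i in range(K):
                for j in range(K):
                    theta[spec.B_idx[t, i, j]] = rng.uniform(-0.5, 0.5)
        theta[spec.varg_idx] = rng.uniform(0.5, 2.0)
        for j in np.asarray(spec.b_idx).ravel():
            theta[j] = rng.normal() * 0.3
        _, Sigma = implied_moments(spec, theta)
        assert np.allclose(Sigma, Sigma.T)
        assert np.linalg.eigvalsh(Sigma)[0] >= -1e-10

    def test_monte_carlo_moments_match(self):
        # sample moments of a large simulated cohort agree with the implied
        # moments within 3 standard errors elementwise
        rng = np.random.default_rng(99)
        K, T, n = 2, 3, 100_000
        A = rng.normal(size=(K, K)) * 0.1

        def psd(scale):
            M = rng.normal(size=(K, K)) * scale
            return M @ M.T + scale * np.eye(K)

        params = TrueParameters(
            construct_labels=("c1", "c2"),
            n_waves=T,
            mu=rng.normal(size=(K, T)),
            b=np.array([0.2, -0.1]),
            var_g=1.0,
            Psi=psd(0.3),
            Sw1=psd(0.3),
            B=np.stack([A, A * 0.5]),
            Theta=np.stack([psd(0.2), psd(0.2)]),
            participation=(1.0, 1.0, 1.0),
            genotyped_share=1.0,
            stillbirth_rate=0.0,
            never_participation_rate=0.0,
        ).validate()
        spec = build_model(params.model_config(scheme="free"))
        theta = true_theta(params, spec)
        mu, Sigma = implied_moments(spec, theta)
        cohort = simulate_cohort(params, n, seed=5, items=False)
        X = cohort.panel[spec.variable_names].to_numpy()
        se_mean = np.sqrt(np.diag(Sigma) / n)
        assert np.all(np.abs(X.mean(0) - mu) < 3.5 * se_mean)
        S = np.cov(X.T, ddof=0)
        d = np.sqrt(np.diag(Sigma))
        se_cov = np.sqrt((np.outer(d, d) ** 2 + Sigma**2) / n)  # normal-theory SE
        assert np.all(np.abs(S - Sigma) < 3.5 * se_cov)

    def test_nonpsd_residual_block_rejected(self):
        spec = build_model(ModelConfig(2, 3, scheme="free"))
        theta = spec.start_vector()
        theta[spec.theta_idx[1, 0, 1]] = 5.0  # covariance far above variances
        with pytest.raises(ValueError, match="wave 3"):
            implied_moments(spec, theta, validate=True)


class TestStandardize:
    def test_compound_symmetry_loading(self):
        spec = build_model(ModelConfig(1, 4, scheme="free"))
        theta = _theta_by_label(
            spec, psi_c1=0.6, sw1_c1=0.4, theta_t2_c1=0.4, theta_t3_c1=0.4, theta_t4_c1=0.4
        )
        std = standardize(spec, theta)
        assert np.allclose(std["ri_loading_std"], np.sqrt(0.6))
        assert np.allclose(std["ri_corr"], 1.0)

    def test_equal_variance_paths_unchanged(self):
        # equal within-process variances across waves: standardized = raw
        spec = build_model(ModelConfig(1, 2, scheme="free"))
        theta = _theta_by_label(spec, sw1_c1=1.0, theta_t2_c1=0.91)
        labels = list(spec.params["label"])
        theta[labels.index("beta_t2_c1~c1")] = 0.3  # var(w2)=0.09+0.91=1
        std = standardize(spec, theta)
        assert std["transitions_std"][0, 0, 0] == pytest.approx(0.3)

    def test_ri_correlation_unit_diagonal(self):
        spec = build_model(ModelConfig(3, 3, scheme="free"))
        theta = spec.start_vector()
        std = standardize(spec, theta)
        assert np.allclose(np.diag(std["ri_corr"]), 1.0)


class TestSerialization:
    def test_json_round_trip(self):
        spec = build_model(
            ModelConfig(2, 4, scheme="first_free", predictor="on_random_intercepts",
                        construct_labels=("relsat", "dep"))
        )
        text = spec.to_json()
        back = ModelSpec.from_json(text)
        assert back.config == spec.config
        assert list(back.params["label"]) == list(spec.params["label"])
        assert back.n_free == spec.n_free
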