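"""Scoring, reliability and correlation operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from riclpm.scales import (
    SCALES,
    composite_score,
    correlation_matrix,
    cronbach_alpha,
    log_transform,
    partial_correlation,
    score_items,
)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "items, expected",
        [
            ((3, 3, 3), 3.0),
            ((1, 2, 3, 4, 5, 6, np.nan, 4, 2, 3), 30 / 9),
        ],
    )
    def test_mean_of_observed_items(self, items, expected):
        assert composite_score(items, min_fraction=0.5) == pytest.approx(expected)

    def test_all_missing_gives_missing(self):
        assert np.isnan(composite_score([np.nan, np.nan, np.nan]))

    def test_below_min_fraction_gives_missing(self):
        items = [4.0] + [np.nan] * 9  # 10% answered
        assert np.isnan(composite_score(items, min_fraction=0.5))

    def test_empty_items_error(self):
        with pytest.raises(ValueError, match="no items"):
            composite_score([])

    @given(st.lists(st.integers(1, 6), min_size=2, max_size=10), st.randoms())
    def test_invariant_to_item_order_and_bounded(self, items, rnd):
        a = composite_score(items)
        shuffled = list(items)
        rnd.shuffle(shuffled)
        assert composite_score(shuffled) == pytest.approx(a)
        assert min(items) <= a <= max(items)


class TestCronbachAlpha:
    def test_duplicated_columns_give_one(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        assert cronbach_alpha(np.hstack([x, x])) == pytest.approx(1.0)

    def test_exchangeable_covariance_closed_form(self):
        # three items, unit variances, pairwise covariances 0.5:
        # alpha = (3/2) * (1 - 3/6) = 0.75 on the population covariance
        cov = np.full((3, 3), 0.5)
        np.fill_diagonal(cov, 1.0)
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        assert cronbach_alpha(X) == pytest.approx(0.75, abs=0.01)

    def test_independent_items_give_zero(self):
        X = np.random.default_rng(1).normal(size=(100_000, 4))
        assert cronbach_alpha(X) == pytest.approx(0.0, abs=0.02)

    def test_one_factor_population_formula(self):
        # items y_j = lambda f + e_j with unit uniqueness: population
        # alpha = p*lam2/(p*lam2 + 1) adjusted through the standard formula
        lam, p, n = 0.8, 5, 100_000
        rng = np.random.default_rng(11)
        f = rng.normal(size=n)
        X = lam * f[:, None] + rng.normal(size=(n, p))
        rbar = lam**2 / (lam**2 + 1.0)
        expected = p * rbar / (1 + (p - 1) * rbar)
        assert cronbach_alpha(X) == pytest.approx(expected, abs=0.02)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        f = rng.normal(size=300)
        X = pd.DataFrame(f[:, None] + rng.normal(size=(300, 4)))
        ours = cronbach_alpha(X.to_numpy())
        theirs = pingouin.cronbach_alpha(data=X)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_degenerate_scale_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            cronbach_alpha(np.ones((10, 3)))


class TestLogTransform:
    @pytest.mark.parametrize("x, expected", [(1.0, 0.0), (np.e, 1.0)])
    def test_analytic_values(self, x, expected):
        assert log_transform(x) == pytest.approx(expected)

    def test_missing_passes_through(self):
        assert np.isnan(log_transform(np.nan))

    def test_below_scale_minimum_error(self):
        with pytest.raises(ValueError, match="below scale minimum"):
            log_transform(0.5)

    @given(st.lists(st.floats(1.0, 6.0), min_size=2, max_size=20, unique=True))
    def test_preserves_rank_order(self, xs):
        xs = np.array(xs)
        assert np.array_equal(np.argsort(log_transform(xs)), np.argsort(xs))


class TestCorrelationMatrix:
    def test_unit_diagonal_and_anticorrelated_pair(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": -x})
        corr = correlation_matrix(df)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_columns_sampling_bound(self):
        n = 100_000
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        assert abs(correlation_matrix(df).loc["a", "b"]) < 3 / np.sqrt(n)

    def test_sparse_overlap_flagged_missing(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, np.nan, 1.0, 2.0]}
        )
        with pytest.warns(UserWarning, match="overlapping"):
            corr = correlation_matrix(df)
        assert np.isnan(corr.loc["a", "b"])

    def test_pairwise_uses_more_cases_than_listwise(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        df.loc[:150, "c"] = np.nan  # listwise would drop 151 rows
        pw = correlation_matrix(df, method="pairwise")
        lw = correlation_matrix(df, method="listwise")
        assert pw.loc["a", "b"] != pytest.approx(lw.loc["a", "b"], abs=1e-12)


class TestPartialCorrelation:
    def test_single_covariate_closed_form(self):
        # r_xy = r_xz = r_yz = 0.5 -> partial = (0.5 - 0.25) / 0.75 = 1/3
        cov = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1.0]])
        rng = np.random.default_rng(13)
        X = rng.multivariate_normal(np.zeros(3), cov, size=400_000)
        r = partial_correlation(X[:, 0], X[:, 1], X[:, 2])
        assert r == pytest.approx(1 / 3, abs=0.01)

    def test_empty_covariates_equal_plain_correlation(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=(2, 500))
        df = pd.DataFrame({"x": x, "y": y})
        assert partial_correlation(x, y) == pytest.approx(
            correlation_matrix(df).loc["x", "y"], abs=1e-12
        )

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        assert partial_correlation(x, x, z) == pytest.approx(1.0)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        df = pd.DataFrame(rng.normal(size=(300, 4)), columns=["x", "y", "z1", "z2"])
        df["y"] += 0.5 * df["x"] + 0.3 * df["z1"]
        ours = partial_correlation(df["x"], df["y"], df[["z1", "z2"]])
        theirs = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])["r"].iloc[0]
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_collinear_covariates_error(self):
        rng = np.random.default_rng(29)
        x, y, z = rng.normal(size=(3, 50))
        with pytest.raises(ValueError, match="singular"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


class TestScoreItems:
    def test_wave4_relsat_has_five_items_and_same_metric(self):
        assert SCALES["relsat"].n_items(4) == 5
        assert SCALES["relsat"].n_items(1) == 10

    def test_scores_item_table(self):
        rng = np.random.default_rng(31)
        cols = {}
        for c, scale in SCALES.items():
            for t in (1, 2, 3, 4):
                for i in range(1, scale.n_items(t) + 1):
                    cols[f"{c}_{i:02d}_t{t}"] = rng.integers(
                        scale.response_min, scale.response_max + 1, size=8
                    ).astype(float)
        items = pd.DataFrame(cols)
        items.loc[0, [f"relsat_{i:02d}_t1" for i in range(1, 10)]] = np.nan  # 1/10 left
        panel = score_items(items)
        assert panel.shape[1] == 16
        assert np.isnan(panel.loc[0, "relsat_t1"])  # below the half-items rule
        manual = items.loc[1, [f"posaff_{i:02d}_t2" for i in (1, 2, 3)]].mean()
        assert panel.loc[1, "posaff_t2"] == pytest.approx(manual)

    def test_out_of_range_item_rejected(self):
        items = pd.DataFrame({f"posaff_{i:02d}_t{t}": [9.0] for i in (1, 2, 3) for t in (1, 2, 3, 4)})
        with pytest.raises(ValueError, match="outside"):
            score_items(items, constructs=("posaff",))
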