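"""3-step structural models, effect sizes and contrast algebra."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from trajmix.three_step import (
    PredictorEffect,
    fit_adjusted,
    fit_step3_distal,
    fit_step3_predictor,
    modal_assign,
    odds_ratio,
    pairwise_contrast,
    pseudo_r,
    standardized_outcome_regression,
)


def onehot(labels, K):
    post = np.zeros((len(labels), K))
    post[np.arange(len(labels)), labels] = 1.0
    return post


def draw_classes(rng, x, alpha, gamma):
    """Multinomial logistic draw (class 1 = reference)."""
    logits = np.column_stack([np.zeros(len(x)), alpha + np.outer(x, gamma)])
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    return (rng.random(len(x))[:, None] > p.cumsum(axis=1)).sum(axis=1)


class TestModalAssign:
    def test_onehot_gives_identity_q(self):
        a = modal_assign(onehot(np.array([0, 1, 2, 1]), 3))
        np.testing.assert_allclose(a.Q, np.eye(3))
        # off-diagonal logits are at the floor-implied minimum
        assert a.logits[0, 1] == pytest.approx(np.log(1e-8) - np.log(1e-8))
        assert a.logits[0, 0] == pytest.approx(np.log(1.0) - np.log(1e-8))

    def test_two_class_toy_matches_hand_computation(self):
        post = np.array([[0.9, 0.1], [0.4, 0.6], [0.8, 0.2]])
        a = modal_assign(post)
        np.testing.assert_array_equal(a.modal, [0, 1, 0])
        # q_st = sum_i p_is 1[N_i=t] / sum_i p_is, computed by hand:
        # col sums: class1 mass = 2.1, class2 mass = 0.9
        expected = np.array([
            [(0.9 + 0.8) / 2.1, 0.4 / 2.1],
            [(0.1 + 0.2) / 0.9, 0.6 / 0.9],
        ])
        np.testing.assert_allclose(a.Q, expected, atol=1e-12)

    def test_tie_goes_to_lowest_class(self):
        a = modal_assign(np.array([[0.5, 0.5], [0.1, 0.9]]))
        assert a.modal[0] == 0

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            modal_assign(np.array([[0.5, 0.4], [0.3, 0.7]]))

    def test_empty_modal_class_named_in_error(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        with pytest.raises(ValueError, match="class 2"):
            modal_assign(post)


@pytest.fixture(scope="module")
def identity_setup():
    rng = np.random.default_rng(5)
    n = 600
    x = rng.normal(0, 1, n)
    C = draw_classes(rng, x, np.array([0.2, -0.3]), np.array([0.8, -0.5]))
    return x, C, modal_assign(onehot(C, 3))


@pytest.fixture(scope="module")
def identity_distal():
    rng = np.random.default_rng(8)
    n, K = 500, 3
    C = rng.choice(K, n, p=[0.4, 0.35, 0.25])
    y = np.array([0.0, 1.0, 3.0])[C] + rng.normal(0, 0.7, n)
    return C, y, modal_assign(onehot(C, K))


class TestPredictorModel:
    def test_identity_q_matches_classical_multinomial(self, identity_setup):
        """With one-hot posteriors the fixed-error fit IS multinomial logistic."""
        x, C, a = identity_setup
        eff = fit_step3_predictor(a, x)
        oracle = sm.MNLogit(C, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(eff.gamma[1:], np.asarray(oracle.params)[1], atol=1e-4)
        null = sm.MNLogit(C, np.ones((len(x), 1))).fit(disp=0)
        assert eff.chi2 == pytest.approx(2 * (oracle.llf - null.llf), abs=1e-4)

    def test_df_is_k_minus_one(self, identity_setup):
        _, _, a = identity_setup
        eff = fit_step3_predictor(a, np.random.default_rng(0).normal(size=a.n))
        assert eff.df == 2

    def test_df_is_eight_for_nine_classes(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(np.arange(9), 30)
        a = modal_assign(onehot(labels, 9))
        eff = fit_step3_predictor(a, rng.normal(size=a.n))
        assert eff.df == 8

    def test_separation_flagged_and_penalized(self):
        """A perfectly class-separating predictor triggers the ridge fallback."""
        C = np.repeat([0, 1, 2], 40)
        a = modal_assign(onehot(C, 3))
        eff = fit_step3_predictor(a, C.astype(float))
        assert eff.penalized
        assert np.isfinite(eff.gamma).all()

    def test_constant_predictor_rejected(self, identity_setup):
        _, _, a = identity_setup
        with pytest.raises(ValueError, match="constant"):
            fit_step3_predictor(a, np.ones(a.n))

    def test_lrt_null_calibration(self):
        """Zeroing LRT follows chi-square(K-1) under a null predictor."""
        K, n, sims = 3, 200, 200
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(sims):
            # soft posteriors -> non-identity Q
            true = rng.choice(K, n, p=[0.5, 0.3, 0.2])
            noise = rng.dirichlet(np.ones(K) * 0.6, size=n)
            post = 0.75 * onehot(true, K) + 0.25 * noise
            post /= post.sum(axis=1, keepdims=True)
            a = modal_assign(post)
            x = rng.normal(size=n)  # independent of class
            eff = fit_step3_predictor(a, x)
            rejections += eff.p_value <= 0.05
        lo, hi = stats.binom.interval(0.95, sims, 0.05)
        assert lo <= rejections <= hi


class TestDistalModel:
    def test_identity_q_recovers_per_class_sample_means(self, identity_distal):
        C, y, a = identity_distal
        eff = fit_step3_distal(a, y)
        oracle = np.array([y[C == k].mean() for k in range(3)])
        np.testing.assert_allclose(eff.class_means, oracle, atol=1e-6)

    def test_reference_standardized_difference_is_zero(self, identity_distal):
        _, y, a = identity_distal
        eff = fit_step3_distal(a, y)
        assert eff.std_diffs[0] == 0.0

    def test_r_matches_variance_decomposition(self, identity_distal):
        _, y, a = identity_distal
        eff = fit_step3_distal(a, y)
        assert eff.r == pytest.approx(
            np.sqrt(1 - eff.sigma2_within / np.var(y)), abs=1e-12
        )
        assert 0.0 <= eff.r <= 1.0

    def test_equal_means_null_case(self):
        rng = np.random.default_rng(3)
        n, K = 400, 3
        C = rng.choice(K, n)
        y = rng.normal(0, 1, n)  # no class effect
        eff = fit_step3_distal(modal_assign(onehot(C, K)), y)
        assert eff.r < 0.15
        assert eff.chi2 < stats.chi2.ppf(0.999, K - 1)

    def test_pairwise_count_for_nine_classes(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(np.arange(9), 25)
        a = modal_assign(onehot(labels, 9))
        eff = fit_step3_distal(a, rng.normal(size=a.n))
        assert len(eff.pairwise_tests()) == 36


class TestAdjustedModel:
    def test_single_predictor_nesting_matches_unadjusted_lrt(self):
        rng = np.random.default_rng(9)
        n = 400
        x = rng.normal(0, 1, n)
        C = draw_classes(rng, x, np.array([0.0, -0.2]), np.array([0.7, -0.4]))
        noise = rng.dirichlet(np.ones(3) * 0.5, size=n)
        post = 0.8 * onehot(C, 3) + 0.2 * noise
        post /= post.sum(axis=1, keepdims=True)
        a = modal_assign(post)
        eff = fit_step3_predictor(a, x)
        adj = fit_adjusted(a, x.reshape(-1, 1), y=None, predictor_names=["x"])
        assert adj.predictor_lrt["x"]["chi2"] == pytest.approx(eff.chi2, abs=1e-6)

    def test_purely_indirect_predictor(self):
        """A predictor acting only through class keeps a near-zero direct path."""
        rng = np.random.default_rng(10)
        n = 1500
        x = rng.normal(0, 1, n)
        gamma = np.array([1.0, 1.6])
        C = draw_classes(rng, x, np.array([0.0, -0.4]), gamma)
        means = np.array([0.0, 1.0, 2.5])
        y = means[C] + rng.normal(0, 0.8, n)
        a = modal_assign(onehot(C, 3))
        adj = fit_adjusted(a, x.reshape(-1, 1), y, predictor_names=["x"],
                           lrt_predictors=False)
        assert abs(adj.direct[0]) < 0.1
        np.testing.assert_allclose(adj.Gamma[:, 0], gamma, atol=0.25)
        np.testing.assert_allclose(adj.class_means, means, atol=0.15)

    def test_direct_zero_constraint(self):
        rng = np.random.default_rng(11)
        n = 300
        x = rng.normal(0, 1, n)
        C = draw_classes(rng, x, np.zeros(2), np.array([0.5, 0.8]))
        y = C.astype(float) + 0.5 * x + rng.normal(0, 1, n)
        a = modal_assign(onehot(C, 3))
        adj = fit_adjusted(a, x.reshape(-1, 1), y, direct_zero=[0], lrt_predictors=False)
        assert adj.direct[0] == 0.0

    def test_trajectory_lrt_reduces_to_unadjusted_distal_without_predictors_effects(self):
        """Removing all predictor effects reproduces the unadjusted distal fit."""
        rng = np.random.default_rng(12)
        n, K = 500, 3
        C = rng.choice(K, n, p=[0.4, 0.35, 0.25])
        y = np.array([0.0, 0.8, 2.0])[C] + rng.normal(0, 0.7, n)
        a = modal_assign(onehot(C, K))
        x = rng.normal(size=n)  # pure noise predictor, zero direct path
        adj = fit_adjusted(a, x.reshape(-1, 1), y, direct_zero=[0], lrt_predictors=False)
        unadj = fit_step3_distal(a, y)
        np.testing.assert_allclose(adj.class_means, unadj.class_means, atol=0.05)

    def test_rank_deficient_predictors_rejected(self):
        a = modal_assign(onehot(np.array([0, 1, 0, 1] * 10), 2))
        x = np.ones((40, 2))
        x[:, 0] = np.arange(40)
        x[:, 1] = 2 * x[:, 0]
        with pytest.raises(ValueError, match="rank"):
            fit_adjusted(a, x, y=None)


class TestEffectSizeAlgebra:
    def test_pseudo_r_zero(self):
        assert pseudo_r(0.0, 500) == 0.0

    def test_pseudo_r_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pseudo_r(-1.0, 10)
        with pytest.raises(ValueError):
            pseudo_r(1.0, 0)

    @given(st.floats(0.1, 500.0), st.floats(0.1, 500.0), st.integers(10, 10_000))
    def test_pseudo_r_monotone_and_scales_with_sqrt_n(self, c1, c2, n):
        if c1 < c2:
            assert pseudo_r(c1, n) <= pseudo_r(c2, n)
        assert pseudo_r(c1, 4 * n) == pytest.approx(pseudo_r(c1, n) / 2)

    def test_contrast_antisymmetry_and_self_zero(self):
        eff = PredictorEffect(
            gamma=np.zeros(4), std_gamma=np.array([0.0, 0.3, -0.1, 0.5]),
            chi2=1.0, df=3, p_value=0.5, omega=0.1,
            cov_std=np.eye(3) * 0.01, sd_x=1.0,
        )
        c12 = pairwise_contrast(eff, 2, 3)[0]
        c21 = pairwise_contrast(eff, 3, 2)[0]
        assert c12 == -c21
        assert pairwise_contrast(eff, 2, 2)[0] == 0.0

    def test_contrast_with_reference_equals_printed_coefficient(self):
        eff = PredictorEffect(
            gamma=np.zeros(3), std_gamma=np.array([0.0, 0.42, -0.17]),
            chi2=1.0, df=2, p_value=0.5, omega=0.1,
            cov_std=np.eye(2) * 0.01, sd_x=1.0,
        )
        assert pairwise_contrast(eff, 2, 1)[0] == pytest.approx(0.42)

    def test_odds_ratio_identity(self):
        assert odds_ratio(0.0) == 1.0

    def test_odds_ratio_requires_finite(self):
        with pytest.raises(ValueError):
            odds_ratio(np.inf)


class TestStandardizedRegression:
    def test_perfect_line_gives_one(self):
        x = np.linspace(0, 1, 30)
        assert standardized_outcome_regression(x, x.copy()) == pytest.approx(1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(standardized_outcome_regression(x, y)) < 0.03

    def test_matches_pearson_correlation_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([0.3, -0.1, 0.8, 1.1, 0.9])
        # closed-form r computed by hand from covariances
        r = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert standardized_outcome_regression(x, y) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardized_outcome_regression(np.ones(5), np.arange(5.0))
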