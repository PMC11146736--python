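"""LCGA core: likelihood, EM, prediction, diagnostics."""

import math

import numpy as np
import pytest

from conftest import B3, PI3, make_mixture_panel
from trajmix.lcga import (
    AGE_CENTER,
    FitSettings,
    LcgaModel,
    TrajectoryPanel,
    _random_start,
    _run_em,
    classification_diagnostics,
    fit_lcga,
    loglik,
    posterior_matrix,
    predicted_curve,
    relabel,
)


def tiny_model(K, B, pi, sigma2, n_children=1):
    return LcgaModel(
        K=K, B=np.asarray(B, float), sigma2=sigma2, pi=np.asarray(pi, float),
        loglik=0.0, posterior=np.full((n_children, K), 1.0 / K),
        children=np.arange(n_children),
    )


class TestLoglik:
    def test_hand_computed_two_class_mixture(self):
        """One child, two observations, K=2: matches a by-hand mixture density."""
        panel = TrajectoryPanel([0, 0], [2.2, 3.2], [0.5, -0.3])
        B = np.array([[0.0, 0, 0, 0, 0], [1.0, -1.0, 0, 0, 0]])
        pi = np.array([0.3, 0.7])
        sigma2 = 0.5
        model = tiny_model(2, B, pi, sigma2)

        def norm_pdf(x, mu):
            return math.exp(-0.5 * (x - mu) ** 2 / sigma2) / math.sqrt(2 * math.pi * sigma2)

        # class 1 mean curve is 0; class 2 is 1 - (age - 2.2)
        like = 0.3 * norm_pdf(0.5, 0.0) * norm_pdf(-0.3, 0.0) + 0.7 * norm_pdf(
            0.5, 1.0
        ) * norm_pdf(-0.3, 0.0)
        assert loglik(model, panel) == pytest.approx(math.log(like), abs=1e-10)

    def test_zero_weight_class_leaves_loglik_unchanged(self):
        panel = TrajectoryPanel([0, 0, 1], [1.5, 3.0, 2.0], [0.1, 0.4, -0.2])
        B = np.array([[0.2, 0, 0, 0, 0]])
        base = tiny_model(1, B, [1.0], 0.8, n_children=2)
        padded = tiny_model(
            2, np.vstack([B, [5.0, 0, 0, 0, 0]]), [1.0, 0.0], 0.8, n_children=2
        )
        assert loglik(padded, panel) == pytest.approx(loglik(base, panel), abs=1e-12)

    def test_single_class_equals_sum_of_normal_logdensities(self):
        rng = np.random.default_rng(0)
        panel = TrajectoryPanel(np.repeat(np.arange(5), 3), rng.uniform(1, 5, 15), rng.normal(size=15))
        B = np.array([[0.3, -0.1, 0.05, 0.0, 0.01]])
        model = tiny_model(1, B, [1.0], 1.3, n_children=5)
        X = np.vander(panel.age - AGE_CENTER, 5, increasing=True)
        resid = panel.score - X @ B[0]
        direct = np.sum(-0.5 * (np.log(2 * np.pi * 1.3) + resid**2 / 1.3))
        assert loglik(model, panel) == pytest.approx(direct, abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        panel = TrajectoryPanel([0], [2.0], [0.1])
        model = tiny_model(1, np.zeros((1, 5)), [1.0], 1.0)
        model.sigma2 = -1.0
        with pytest.raises(ValueError, match="sigma2"):
            loglik(model, panel)


class TestPredictedCurve:
    def test_center_age_returns_intercept(self):
        model = tiny_model(2, [[1.7, 2, 3, 4, 5], [0.4, 1, 1, 1, 1]], [0.5, 0.5], 1.0)
        assert predicted_curve(model, 1, [2.2])[0] == pytest.approx(1.7)
        assert predicted_curve(model, 2, [2.2])[0] == pytest.approx(0.4)

    def test_constant_row(self):
        model = tiny_model(1, [[1.0, 0, 0, 0, 0]], [1.0], 1.0)
        np.testing.assert_allclose(predicted_curve(model, 1, np.linspace(1, 5, 9)), 1.0)

    def test_matches_naive_polynomial_oracle(self):
        row = np.array([0.3, -1.2, 0.8, -0.21, 0.017])
        model = tiny_model(1, [row], [1.0], 1.0)
        ages = np.linspace(0.6, 5.4, 50)
        naive = np.array([sum(row[p] * (a - 2.2) ** p for p in range(5)) for a in ages])
        assert np.abs(predicted_curve(model, 1, ages) - naive).max() < 1e-12

    def test_class_index_out_of_range(self):
        model = tiny_model(1, [[0, 0, 0, 0, 0]], [1.0], 1.0)
        with pytest.raises(ValueError, match="class"):
            predicted_curve(model, 2, [2.0])


class TestEm:
    def test_single_class_equals_closed_form_least_squares(self):
        rng = np.random.default_rng(3)
        panel, _ = make_mixture_panel(rng, B3, PI3, 200, 6, sigma=0.8)
        model = fit_lcga(panel, 1, FitSettings(n_starts=1, seed=0))
        X = np.vander(panel.age - AGE_CENTER, 5, increasing=True)
        bhat = np.linalg.lstsq(X, panel.score, rcond=None)[0]
        assert np.abs(model.B[0] - bhat).max() < 1e-6

    def test_three_class_recovery(self, three_class_panel):
        panel, classes = three_class_panel
        model = fit_lcga(panel, 3, FitSettings(n_starts=8, seed=2))
        order = np.argsort(B3 @ np.vander([5.0 - AGE_CENTER], 5, increasing=True)[0])
        assert np.abs(model.B - B3[order]).max() < 0.1
        # proportions match the realized class frequencies of this panel
        freq = np.bincount(classes, minlength=3) / len(classes)
        assert np.abs(model.pi - freq[order]).max() < 0.02

    def test_fitted_loglik_dominates_generating_parameters(self, three_class_panel):
        panel, _ = three_class_panel
        model = fit_lcga(panel, 3, FitSettings(n_starts=8, seed=2))
        generating = tiny_model(3, B3, PI3, 0.8**2, n_children=panel.n_children)
        assert model.loglik >= loglik(generating, panel)

    def test_loglik_monotone_along_em_path(self):
        rng = np.random.default_rng(7)
        panel, _ = make_mixture_panel(rng, B3, PI3, 120, 5, sigma=1.0)
        track = []
        B0, s0, pi0 = _random_start(panel, 2, np.random.default_rng(1))
        _run_em(panel, 2, B0, pi0, s0, FitSettings(n_starts=1, seed=0), track=track)
        assert np.all(np.diff(track) >= -1e-8)

    def test_noiseless_data_hits_variance_floor_with_onehot_posteriors(self):
        rng = np.random.default_rng(5)
        panel, _ = make_mixture_panel(rng, B3[:2], [0.5, 0.5], 80, 6, sigma=0.0)
        model = fit_lcga(panel, 2, FitSettings(n_starts=4, seed=0))
        assert model.sigma2 == pytest.approx(1e-6)
        assert np.allclose(model.posterior.max(axis=1), 1.0)

    def test_relabeling_orders_by_age5_endpoint_and_preserves_loglik(self):
        rng = np.random.default_rng(9)
        panel, _ = make_mixture_panel(rng, B3, PI3, 150, 6, sigma=0.8)
        model = fit_lcga(panel, 3, FitSettings(n_starts=5, seed=4))
        t5 = np.vander([5.0 - AGE_CENTER], 5, increasing=True)[0]
        assert np.all(np.diff(model.B @ t5) > 0)
        # permuting labels then relabeling restores the same ordering and loglik
        perm = np.array([2, 0, 1])
        Bp, pip, postp, _ = relabel(model.B[perm], model.pi[perm], model.posterior[:, perm])
        np.testing.assert_allclose(Bp, model.B)
        shuffled = tiny_model(3, model.B[perm], model.pi[perm], model.sigma2,
                              n_children=panel.n_children)
        straight = tiny_model(3, model.B, model.pi, model.sigma2,
                              n_children=panel.n_children)
        assert loglik(shuffled, panel) == pytest.approx(loglik(straight, panel), abs=1e-9)

    def test_n_params_formula(self):
        model = tiny_model(4, np.zeros((4, 5)), np.full(4, 0.25), 1.0)
        assert model.n_params == 5 * 4 + 3 + 1

    def test_posterior_matrix_rows_sum_to_one(self, three_class_panel):
        panel, _ = three_class_panel
        post = posterior_matrix(panel, B3, 0.64, PI3)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestDiagnostics:
    def test_onehot_entropy_is_one(self):
        post = np.eye(3)[np.array([0, 1, 2, 1, 0])]
        model = tiny_model(3, np.zeros((3, 5)), np.full(3, 1 / 3), 1.0, n_children=5)
        model.posterior = post
        d = classification_diagnostics(model)
        assert d["relative_entropy"] == pytest.approx(1.0)
        assert d["modal_sizes"].sum() == 5

    def test_uniform_entropy_is_zero(self):
        model = tiny_model(4, np.zeros((4, 5)), np.full(4, 0.25), 1.0, n_children=6)
        assert classification_diagnostics(model)["relative_entropy"] == pytest.approx(0.0)

    def test_random_posteriors_match_direct_formula(self):
        rng = np.random.default_rng(2)
        post = rng.dirichlet(np.ones(3), size=40)
        model = tiny_model(3, np.zeros((3, 5)), np.full(3, 1 / 3), 1.0, n_children=40)
        model.posterior = post
        direct = 1.0 - (-(post * np.log(post)).sum()) / (40 * np.log(3))
        assert classification_diagnostics(model)["relative_entropy"] == pytest.approx(direct)


class TestPanelValidation:
    def test_duplicate_child_age_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TrajectoryPanel([0, 0], [2.0, 2.0], [0.1, 0.2])

    def test_age_range_enforced(self):
        with pytest.raises(ValueError, match="ages"):
            TrajectoryPanel([0], [0.2], [0.1])

    def test_too_few_observations_for_k(self):
        panel = TrajectoryPanel([0, 0, 1], [1.5, 3.0, 2.0], [0.1, 0.4, -0.2])
        with pytest.raises(ValueError, match="too few"):
            fit_lcga(panel, 2, FitSettings(n_starts=1, seed=0))
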