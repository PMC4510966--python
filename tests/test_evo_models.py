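"""BM / multi-regime OU likelihoods, fits and AICc comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from handevol import (
    aicc,
    bm_covariance,
    bm_loglik,
    compare_models,
    fit_bm,
    fit_hansen,
    hansen_loglik,
    hansen_weights,
    multivariate_fit,
    ou_covariance,
    read_newick,
)
from handevol.synthetic import sim_tree, simulate_ou
from handevol.tree import paint_clades, uniform_painting

from conftest import (
    bm_cov_oracle,
    hansen_mean_oracle,
    ou_cov_oracle,
    random_ou_fixture,
    star_tree,
)


class TestBMCovariance:
    def test_star_tree_diagonal(self):
        C = bm_covariance(star_tree(5, 2.5)).matrix
        np.testing.assert_allclose(C, 2.5 * np.eye(5))

    def test_three_tip_paths(self, three_tip):
        C = bm_covariance(three_tip).matrix
        labels = three_tip.tip_labels
        a, b, c = (labels.index(l) for l in "ABC")
        assert C[a, b] == pytest.approx(1.0)
        assert C[a, a] == pytest.approx(2.0)
        assert C[a, c] == pytest.approx(0.0)

    def test_matches_pairwise_walk_oracle(self):
        t = sim_tree(8, 6.0, seed=11)
        np.testing.assert_allclose(bm_covariance(t).matrix, bm_cov_oracle(t))


class TestBMLoglik:
    def test_two_tip_independent_normals(self):
        # tips sharing no path: density factorizes into univariate normals
        t = read_newick("(A:1.5,B:2.5);")
        ll = bm_loglik(t, {"A": 0.3, "B": -0.2}, sigma2=0.8, mu=0.1)
        expected = sum(
            -0.5 * (math.log(2 * math.pi * 0.8 * b) + (x - 0.1) ** 2 / (0.8 * b))
            for x, b in [(0.3, 1.5), (-0.2, 2.5)]
        )
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_tip_order_invariance(self):
        t = sim_tree(8, 5.0, seed=3)
        vals = dict(zip(t.tip_labels, np.random.default_rng(0).normal(0, 1, 8)))
        series = pd.Series(vals)
        shuffled = series.sample(frac=1, random_state=1)
        assert bm_loglik(t, series, 1.2, 0.3) == pytest.approx(
            bm_loglik(t, shuffled, 1.2, 0.3)
        )

    def test_dense_mvn_oracle(self):
        t = sim_tree(8, 4.0, seed=21)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 8)
        ll = bm_loglik(t, x, sigma2=0.7, mu=0.4)
        oracle = multivariate_normal.logpdf(
            x, mean=np.full(8, 0.4), cov=0.7 * bm_cov_oracle(t)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestHansenWeights:
    def test_uniform_painting_single_column(self):
        t = sim_tree(6, 3.0, seed=1)
        W = hansen_weights(t, uniform_painting(t), alpha=1.3)
        np.testing.assert_allclose(W, np.ones((6, 1)))

    def test_large_alpha_concentrates_on_terminal_regime(self):
        t = sim_tree(8, 5.0, seed=4)
        p = paint_clades(t, [("r", [t.tip_labels[0], t.tip_labels[1]])])
        W = hansen_weights(t, p, alpha=200.0)
        labels = p.labels
        for k, tip in enumerate(t.tips):
            term_regime = p.branch_regime[tip]
            assert W[k, labels.index(term_regime)] == pytest.approx(1.0, abs=1e-6)

    def test_three_tip_hand_integration_oracle(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        p = paint_clades(t, [("r1", ["A", "B"])])
        alpha = 1.0
        theta = {"background": 0.7, "r1": -1.3}
        W = hansen_weights(t, p, alpha)
        th = np.array([theta[l] for l in p.labels])
        np.testing.assert_allclose(
            W @ th, hansen_mean_oracle(t, p, alpha, theta), atol=1e-10
        )

    @pytest.mark.parametrize("alpha", [1e-6, 1e-3, 1.0, 50.0, 1e3])
    def test_rows_sum_to_one(self, alpha):
        for seed in (5, 6):
            t = sim_tree(10, 5.0, seed=seed)
            p = paint_clades(t, [("r", [t.tip_labels[2], t.tip_labels[5]])])
            W = hansen_weights(t, p, alpha)
            np.testing.assert_allclose(W.sum(axis=1), np.ones(10), atol=1e-10)

    def test_nonpositive_alpha_rejected(self, three_tip):
        with pytest.raises(ValueError):
            hansen_weights(three_tip, uniform_painting(three_tip), 0.0)


class TestOUCovariance:
    def test_unshared_tips_independent(self):
        t = read_newick("(A:2,B:2);")
        V = ou_covariance(t, 1.0, 1.0).matrix
        assert V[0, 1] == pytest.approx(0.0)

    def test_diagonal_closed_form_and_stationary_limit(self):
        T = 3.0
        t = star_tree(4, T)
        V = ou_covariance(t, 0.8, 1.6).matrix
        expected = 1.6 / 1.6 * (1 - math.exp(-1.6 * T))
        assert V[0, 0] == pytest.approx(expected)
        deep = ou_covariance(star_tree(4, 500.0), 0.8, 1.6).matrix
        assert deep[0, 0] == pytest.approx(1.0)  # sigma2 / (2 alpha)

    def test_bm_limit_small_alpha(self):
        t = sim_tree(8, 5.0, seed=8)
        V = ou_covariance(t, 1e-8, 1.0).matrix
        C = bm_covariance(t).matrix
        assert np.abs(V - C).max() < 1e-4

    def test_symmetric_psd_random(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            t = sim_tree(10, 5.0, seed=seed + 50)
            alpha = float(rng.uniform(0.01, 10))
            V = ou_covariance(t, alpha, 1.0).matrix
            np.testing.assert_allclose(V, V.T, atol=1e-12)
            assert np.linalg.eigvalsh(V).min() >= -1e-9 * np.trace(V)


class TestHansenLoglik:
    def test_data_at_optimum_leaves_only_normalizer(self):
        t = sim_tree(6, 4.0, seed=2)
        p = uniform_painting(t)
        theta = {"global": 1.7}
        alpha, sigma2 = 1.2, 0.9
        x = np.full(6, 1.7)
        ll = hansen_loglik(t, p, x, alpha, sigma2, theta)
        V = ou_covariance(t, alpha, sigma2).matrix
        normalizer = -0.5 * (6 * math.log(2 * math.pi) + np.linalg.slogdet(V)[1])
        assert ll == pytest.approx(normalizer, abs=1e-10)

    def test_bm_limit_equivalence(self):
        t = sim_tree(8, 5.0, seed=13)
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 1, 8)
        ll_ou = hansen_loglik(
            t, uniform_painting(t), x, alpha=1e-8, sigma2=1.1, theta={"global": 0.5}
        )
        ll_bm = bm_loglik(t, x, 1.1, 0.5)
        assert abs(ll_ou - ll_bm) < 1e-4

    def test_dense_oracle_random_fixture(self):
        tree, painting, alpha, sigma2, theta, x = random_ou_fixture(seed=77)
        ll = hansen_loglik(tree, painting, x, alpha, sigma2, theta)
        mean = hansen_mean_oracle(tree, painting, alpha, theta)
        cov = ou_cov_oracle(tree, alpha, sigma2)
        oracle = multivariate_normal.logpdf(x, mean=mean, cov=cov)
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestFitBM:
    def test_star_tree_iid_reduction(self):
        t = star_tree(3, 1.0)
        f = fit_bm(t, [1.0, 2.0, 3.0])
        assert f.model.mu == pytest.approx(2.0)
        assert f.model.sigma2 == pytest.approx(2.0 / 3.0)

    def test_constant_trait_flagged(self):
        t = sim_tree(6, 3.0, seed=1)
        f = fit_bm(t, np.full(6, 2.0))
        assert f.model.sigma2 == 0.0
        assert any("degenerate" in fl for fl in f.flags)

    def test_mle_beats_grid_oracle(self):
        t = sim_tree(10, 5.0, seed=30)
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 10)
        f = fit_bm(t, x)
        best = -np.inf
        for s2 in np.geomspace(0.01, 10, 60):
            for mu in np.linspace(-2, 2, 60):
                best = max(best, bm_loglik(t, x, s2, mu))
        assert f.loglik >= best - 1e-6


class TestFitHansen:
    def test_profile_optimal_over_alpha_grid(self):
        tree, painting, alpha, sigma2, theta, _ = random_ou_fixture(seed=9, n_tips=10)
        x = simulate_ou(tree, painting, alpha, sigma2, theta, seed=99).to_numpy()
        f = fit_hansen(tree, painting, x)
        h = tree.height
        for a in np.geomspace(1e-6 / h, 1e3 / h, 25):
            # profile theta by GLS at this alpha, via the public API
            W = hansen_weights(tree, painting, a)
            V = ou_covariance(tree, a, 1.0).matrix
            Vi = np.linalg.inv(V)
            th = np.linalg.solve(W.T @ Vi @ W, W.T @ Vi @ x)
            r = x - W @ th
            s2 = float(r @ Vi @ r) / len(x)
            ll = hansen_loglik(tree, painting, x, a, s2, dict(zip(painting.labels, th)))
            assert f.loglik >= ll - 1e-6

    def test_uniform_painting_bm_data_flags_boundary(self):
        t = sim_tree(12, 5.0, seed=14)
        from handevol.synthetic import simulate_bm

        x = simulate_bm(t, 1.0, 0.0, seed=5)
        f = fit_hansen(t, uniform_painting(t), x)
        if f.model.alpha < 1e-6:
            assert any("BM-like" in fl for fl in f.flags)

    def test_too_few_tips_rejected(self, three_tip):
        with pytest.raises(ValueError):
            fit_hansen(three_tip, uniform_painting(three_tip), [1.0, 2.0, 3.0])


class TestAICc:
    @pytest.mark.parametrize(
        "ll,p,n,expected",
        [(0.0, 1, 10, 2.5), (-5.0, 2, 10, 10 + 4 + 12 / 7)],
    )
    def test_formula(self, ll, p, n, expected):
        assert aicc(ll, p, n) == pytest.approx(expected)

    def test_large_n_limit_is_aic(self):
        assert aicc(-3.0, 4, 10**9) == pytest.approx(6 + 8, abs=1e-6)

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)


class TestCompareModels:
    def _fits(self, aiccs, n=20):
        from handevol.evo_models import BMModel, ModelFit

        return [
            ModelFit(BMModel(1, 0), -a / 2, 2, n, a, name=f"m{i}")
            for i, a in enumerate(aiccs)
        ]

    def test_equal_aicc_equal_weights(self):
        fits = compare_models(self._fits([10.0, 10.0]))
        assert fits[0].akaike_weight == pytest.approx(0.5)

    def test_delta_twenty(self):
        fits = compare_models(self._fits([5.0, 25.0]))
        assert fits[0].delta_aicc == 0.0
        assert fits[1].akaike_weight == pytest.approx(
            math.exp(-10) / (1 + math.exp(-10)), rel=1e-6
        )

    def test_weights_sum_to_one(self):
        fits = compare_models(self._fits([3.0, 9.0, 4.5, 30.0]))
        assert sum(f.akaike_weight for f in fits) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_n_rejected(self):
        fits = self._fits([3.0, 4.0])
        fits[1].n = 19
        with pytest.raises(ValueError):
            compare_models(fits)


class TestMultivariateFit:
    def test_joint_loglik_is_sum_of_univariate(self):
        t = sim_tree(12, 5.0, seed=40)
        p = paint_clades(t, [("r", [t.tip_labels[0], t.tip_labels[3]])])
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {"a": rng.normal(0, 1, 12), "b": rng.normal(0, 1, 12)},
            index=t.tip_labels,
        )
        joint = multivariate_fit(t, p, X)
        solo = [fit_hansen(t, p, X[c]) for c in X]
        assert joint.loglik == pytest.approx(sum(f.loglik for f in solo))
        assert joint.n == 24
        assert joint.n_params == sum(f.n_params for f in solo)
        assert joint.aicc == pytest.approx(
            aicc(joint.loglik, joint.n_params, joint.n)
        )

    def test_extra_regime_never_decreases_loglik(self):
        t = sim_tree(14, 5.0, seed=41)
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.normal(0, 1, 14)}, index=t.tip_labels)
        f1 = multivariate_fit(t, uniform_painting(t), X)
        p2 = paint_clades(t, [("extra", [t.tip_labels[0], t.tip_labels[1]])])
        f2 = multivariate_fit(t, p2, X)
        assert f2.loglik >= f1.loglik - 1e-6
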