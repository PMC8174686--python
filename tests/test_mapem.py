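"""MAP-EM engine: initialization contract, M-step oracles, ascent, recovery."""

import numpy as np
import pytest

from tissuemix import (
    SimConfig,
    TissueMixture,
    default_hyperparameters,
    responsibilities,
    simulate_dataset,
)
from tissuemix import em as em_mod
from tissuemix import mapem
from .conftest import random_mixture


@pytest.fixture
def tiny_problem(rng):
    Y, blocks, theta = random_mixture(rng, n=30, m=(3, 2))
    hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
    theta.hyper = hyper
    gamma = responsibilities(Y, blocks, theta)
    return Y, blocks, theta, gamma, hyper


class TestInitialize:
    def test_variance_split_and_uniform_weights(self, rng):
        Y, blocks, _ = random_mixture(rng, n=50, m=(4, 4))
        hyper = default_hyperparameters(float(np.var(Y)), (4, 4))
        theta = mapem.initialize(Y, blocks, hyper, seed=0)
        var_y = np.var(Y)
        np.testing.assert_allclose(theta.sigma2_eps, 0.95 * var_y)
        np.testing.assert_allclose(theta.sigma2_x, 0.05 * var_y / 4)
        np.testing.assert_allclose(theta.w, [0.5, 0.5])
        np.testing.assert_allclose(theta.alpha, [0.0, 0.0])

    def test_same_seed_same_draws(self, rng):
        Y, blocks, _ = random_mixture(rng, n=50, m=(4, 4))
        hyper = default_hyperparameters(float(np.var(Y)), (4, 4))
        t1 = mapem.initialize(Y, blocks, hyper, seed=9)
        t2 = mapem.initialize(Y, blocks, hyper, seed=9)
        for a, b in zip(t1.tissues, t2.tissues):
            np.testing.assert_array_equal(a.beta, b.beta)

    def test_constant_phenotype_rejected(self, rng):
        _, blocks, _ = random_mixture(rng, n=50, m=(4, 4))
        hyper = default_hyperparameters(1.0, (4, 4))
        with pytest.raises(ValueError, match="constant"):
            mapem.initialize(np.ones(50), blocks, hyper, seed=0)


class TestMStep:
    def test_beta_matches_generalized_ridge_oracle(self, tiny_problem):
        """The beta update must equal an independently assembled ridge solve
        (X' Gamma X + (s2e/s2x) I)^-1 X' Gamma (y - alpha) at iteration-r
        values."""
        Y, blocks, theta, gamma, hyper = tiny_problem
        new = mapem.m_step(Y, blocks, gamma, theta, hyper)
        for k, (block, t_old, t_new) in enumerate(
                zip(blocks, theta.tissues, new.tissues)):
            g = gamma.gamma[:, k]
            X = block.genotypes
            A = X.T @ np.diag(g) @ X + (
                t_old.sigma2_eps / t_old.sigma2_x) * np.eye(block.m)
            rhs = X.T @ (g * (Y - t_old.alpha))
            np.testing.assert_allclose(t_new.beta, np.linalg.solve(A, rhs),
                                       rtol=1e-10)

    def test_scalar_updates_match_printed_formulas(self, tiny_problem):
        Y, blocks, theta, gamma, hyper = tiny_problem
        new = mapem.m_step(Y, blocks, gamma, theta, hyper,
                           sigma2_x_update="plugin")
        n = len(Y)
        for k, (block, t_old, t_new) in enumerate(
                zip(blocks, theta.tissues, new.tissues)):
            g = gamma.gamma[:, k]
            n_k = g.sum()
            Xb = block.genotypes @ t_old.beta
            mu = t_old.alpha + Xb
            assert t_new.w == pytest.approx(n_k / n)
            assert t_new.alpha == pytest.approx(
                g @ (Y - Xb) / (n_k + t_old.sigma2_eps / hyper.sigma2_alpha))
            assert t_new.sigma2_eps == pytest.approx(
                (2 * hyper.b_eps + g @ (Y - mu) ** 2)
                / (n_k + 2 * hyper.a_eps + 1))
            assert t_new.sigma2_x == pytest.approx(
                (t_old.beta @ t_old.beta + 2 * hyper.b_x[k])
                / (block.m + 2 * hyper.a_x + 1))

    def test_em_variance_update_adds_posterior_trace(self, tiny_problem):
        Y, blocks, theta, gamma, hyper = tiny_problem
        em_step = mapem.m_step(Y, blocks, gamma, theta, hyper)
        for k, (block, t_old, t_new) in enumerate(
                zip(blocks, theta.tissues, em_step.tissues)):
            g = gamma.gamma[:, k]
            X = block.genotypes
            A = X.T @ np.diag(g) @ X + (
                t_old.sigma2_eps / t_old.sigma2_x) * np.eye(block.m)
            beta_hat = np.linalg.solve(A, X.T @ (g * (Y - t_old.alpha)))
            e_btb = beta_hat @ beta_hat + t_old.sigma2_eps * np.trace(
                np.linalg.inv(A))
            assert t_new.sigma2_x == pytest.approx(
                (e_btb + 2 * hyper.b_x[k]) / (block.m + 2 * hyper.a_x + 1),
                rel=1e-9)

    def test_vanishing_prior_limit_is_ols(self, rng):
        """With hard assignment and ridge -> 0, beta reduces to per-component
        OLS."""
        Y, blocks, theta, gamma, hyper = None, None, None, None, None
        Y, blocks, theta = random_mixture(rng, n=40, m=(3, 3))
        hyper = default_hyperparameters(float(np.var(Y)), (3, 3))
        theta.hyper = hyper
        import tissuemix.params as p

        hard = p.ResponsibilityMatrix(
            np.column_stack([np.ones(40), np.zeros(40)]))
        theta.tissues[0].sigma2_x = 1e12  # ridge ~ 0
        with pytest.warns(RuntimeWarning, match="degenerate"):
            new = mapem.m_step(Y, blocks, hard, theta, hyper)
        X = blocks[0].genotypes
        ols = np.linalg.lstsq(X, Y - theta.tissues[0].alpha, rcond=None)[0]
        np.testing.assert_allclose(new.tissues[0].beta, ols, rtol=1e-6)

    def test_flat_prior_limit_approaches_em_update(self, rng):
        """As the prior flattens (tiny a, b; huge sigma2_alpha), the MAP
        updates approach Algorithm-2-style maximum-likelihood updates, up to
        the O(1/n_k) denominator difference."""
        from tissuemix.params import Hyperparams

        Y, blocks, theta = random_mixture(rng, n=4000, m=(2, 2))
        flat = Hyperparams(a_x=1e-9, b_x=[1e-12, 1e-12], a_eps=1e-9,
                           b_eps=1e-12, sigma2_alpha=1e12, s=np.ones(2))
        theta.hyper = flat
        for t in theta.tissues:
            t.sigma2_x = 1e9  # remove the ridge
        gamma = responsibilities(Y, blocks, theta)
        map_new = mapem.m_step(Y, blocks, gamma, theta, flat,
                               sigma2_x_update="plugin")
        em_new = em_mod.m_step_em(Y, blocks, gamma, theta)
        for tm_, te in zip(map_new.tissues, em_new.tissues):
            assert tm_.w == pytest.approx(te.w, rel=1e-12)
            assert tm_.alpha == pytest.approx(te.alpha, rel=1e-3)
            assert tm_.sigma2_eps == pytest.approx(te.sigma2_eps, rel=2e-3)
            np.testing.assert_allclose(tm_.beta, te.beta, rtol=1e-4)


class TestFit:
    def test_same_seed_identical_trajectory(self, small_dataset):
        Y, _, blocks = small_dataset
        model = TissueMixture(Y, blocks)
        r1 = model.fit(seed=11)
        r2 = model.fit(seed=11)
        np.testing.assert_array_equal(r1.loglik_trace, r2.loglik_trace)
        np.testing.assert_array_equal(r1.gamma.gamma, r2.gamma.gamma)

    def test_log_posterior_ascent(self, small_dataset):
        """The MAP objective (averaged log-likelihood plus log prior / n)
        must not decrease across sweeps."""
        Y, _, blocks = small_dataset
        n = len(Y)
        hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
        theta = mapem.initialize(Y, blocks, hyper, seed=3)
        from tissuemix.likelihood import log_likelihood

        prev = log_likelihood(Y, blocks, theta, averaged=True) + \
            mapem.log_prior(theta, hyper) / n
        for _ in range(25):
            gamma = responsibilities(Y, blocks, theta)
            theta = mapem.m_step(Y, blocks, gamma, theta, hyper)
            cur = log_likelihood(Y, blocks, theta, averaged=True) + \
                mapem.log_prior(theta, hyper) / n
            assert cur >= prev - 1e-8
            prev = cur

    def test_parameter_recovery(self):
        """Balanced mixing and moderate heritability: fitted weights within
        0.05 of truth and effect estimates correlated with truth, averaged
        over seeds."""
        w_err, corrs = [], []
        for seed in range(5):
            cfg = SimConfig(n=10_000, m=(300, 300), h2=(0.3, 0.3), seed=seed)
            Y, truth, blocks = simulate_dataset(cfg)
            res = TissueMixture(Y, blocks).fit(seed=seed)
            w_err.append(abs(res.params.w[0] - 0.5))
            corrs.append(np.mean([
                np.corrcoef(res.params.tissues[k].beta, truth.beta[k])[0, 1]
                for k in range(2)]))
        assert np.mean(w_err) < 0.05
        assert np.mean(corrs) > 0.5

    def test_variances_stay_positive(self, small_dataset):
        Y, _, blocks = small_dataset
        hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
        theta = mapem.initialize(Y, blocks, hyper, seed=1)
        for _ in range(15):
            gamma = responsibilities(Y, blocks, theta)
            theta = mapem.m_step(Y, blocks, gamma, theta, hyper)
            assert np.all(theta.sigma2_x > 0)
            assert np.all(theta.sigma2_eps > 0)
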