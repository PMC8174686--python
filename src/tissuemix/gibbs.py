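"""Gibbs sampler for the Bayesian mixture of regressions.

Used to estimate the tissue-specific subtype heritability with posterior
uncertainty, which point estimation (MAP-EM) does not provide.  The sampler
cycles the conjugate full conditionals implied by the model's priors; each is
derived in docs/methods.md before it was coded:

    C_i | .        categorical, P(C_i = k) proportional to
                   w_k phi(y_i | alpha_k + x_ki' beta_k, s2e_k)
    w | .          Dirichlet(s + counts)
    alpha_k | .    N(v_k sum_{i: C_i=k}(y_i - x_ki' beta_k) / s2e_k, v_k),
                   v_k = (n_k / s2e_k + 1 / s2a)^-1
    beta_k | .     N_m(Lambda^-1 X_k' (y - alpha_k) / s2e_k, Lambda^-1),
                   Lambda = X_k' X_k / s2e_k + I / s2x_k   (rows with C_i = k)
    s2e_k | .      InvGamma(a_eps + n_k/2, b_eps + RSS_k/2)
    s2x_k | .      InvGamma(a_x + m_k/2, b_x_k + beta_k' beta_k / 2)

A component left empty by the label draw has its parameters refreshed from
the prior.  Per retained draw, the tissue-specific subtype heritability is

    h2_k = m_k s2x_k / (m_k s2x_k + s2e_k),

the fraction of the model-implied subtype variance that is genetic — with
standardized genotypes the genetic variance under component k is m_k s2x_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .params import Hyperparams, MixtureParams, TissueBlock, check_blocks

__all__ = ["GibbsChains", "gibbs_fit", "heritability_posterior"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GibbsChains:
    """Retained posterior draws from the Gibbs sampler.

    ``w``: draws x K; ``alpha``: draws x K; ``beta``: list of K arrays,
    draws x m_k; ``sigma2_x``, ``sigma2_eps``: draws x K; ``C``: draws x n
    integer labels in {0..K-1}.
    """

    w: np.ndarray
    alpha: np.ndarray
    beta: list[np.ndarray]
    sigma2_x: np.ndarray
    sigma2_eps: np.ndarray
    C: np.ndarray
    burn_in: int
    thin: int
    seed: int | None
    tissue_ids: list[str]

    @property
    def n_draws(self) -> int:
        return self.w.shape[0]

    @property
    def K(self) -> int:
        return self.w.shape[1]

    @property
    def m(self) -> np.ndarray:
        return np.array([b.shape[1] for b in self.beta])


def _draw_component_params(rng, k, idx, Y, X, alpha_k, s2e_k, s2x_k, hyper):
    """Draw (alpha, beta, s2e, s2x) for one component given its members."""
    m = X.shape[1]
    n_k = idx.size
    if n_k == 0:
        # empty component: refresh from the prior
        s2x = 1.0 / rng.gamma(hyper.a_x, 1.0 / hyper.b_x[k])
        s2e = 1.0 / rng.gamma(hyper.a_eps, 1.0 / hyper.b_eps)
        alpha = rng.normal(0.0, np.sqrt(hyper.sigma2_alpha))
        beta = rng.normal(0.0, np.sqrt(s2x), size=m)
        return alpha, beta, s2e, s2x
    Xs = X[idx]
    ys = Y[idx]
    # beta | alpha, variances
    prec = Xs.T @ Xs / s2e_k
    prec[np.diag_indices_from(prec)] += 1.0 / s2x_k
    c = sla.cho_factor(prec, lower=True, check_finite=False)
    mean = sla.cho_solve(c, Xs.T @ (ys - alpha_k) / s2e_k, check_finite=False)
    z = rng.standard_normal(m)
    beta = mean + sla.solve_triangular(c[0].T, z, lower=False, check_finite=False)
    # alpha | beta, variances
    resid = ys - Xs @ beta
    v = 1.0 / (n_k / s2e_k + 1.0 / hyper.sigma2_alpha)
    alpha = rng.normal(v * resid.sum() / s2e_k, np.sqrt(v))
    # sigma2_eps | alpha, beta
    rss = float(np.sum((resid - alpha) ** 2))
    s2e = 1.0 / rng.gamma(hyper.a_eps + n_k / 2.0,
                          1.0 / (hyper.b_eps + rss / 2.0))
    # sigma2_x | beta
    s2x = 1.0 / rng.gamma(hyper.a_x + m / 2.0,
                          1.0 / (hyper.b_x[k] + float(beta @ beta) / 2.0))
    return alpha, beta, s2e, s2x


def gibbs_fit(Y: np.ndarray, blocks: list[TissueBlock], hyper: Hyperparams,
              iters: int = 5000, burn_in: int = 2000, thin: int = 1,
              seed: int | None = None,
              init: MixtureParams | None = None) -> GibbsChains:
    """Run the Gibbs sampler and return post-burn-in, thinned chains.

    Initialization mirrors the EM engines (variances from the 5%/95% split,
    beta from its prior) unless explicit starting parameters are supplied.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    check_blocks(blocks)
    if iters <= burn_in:
        raise ValueError("iters must exceed burn_in")
    n = Y.shape[0]
    K = len(blocks)
    rng = np.random.default_rng(seed)

    if init is None:
        from .mapem import initialize

        init = initialize(Y, blocks, hyper, seed=seed)
    w = init.w.copy()
    alpha = init.alpha.copy()
    beta = [t.beta.copy() for t in init.tissues]
    s2e = init.sigma2_eps.copy()
    s2x = init.sigma2_x.copy()

    keep = (iters - burn_in) // thin
    out_w = np.empty((keep, K))
    out_alpha = np.empty((keep, K))
    out_beta = [np.empty((keep, b.m)) for b in blocks]
    out_s2x = np.empty((keep, K))
    out_s2e = np.empty((keep, K))
    out_C = np.empty((keep, n), dtype=np.int32)

    Xs = [b.genotypes for b in blocks]
    kept = 0
    for it in range(iters):
        # C | . : categorical by stabilized log-probabilities
        mu = np.column_stack([alpha[k] + Xs[k] @ beta[k] for k in range(K)])
        logp = (np.log(w) - 0.5 * (_LOG_2PI + np.log(s2e))
                - (Y[:, None] - mu) ** 2 / (2.0 * s2e))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        C = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)

        counts = np.bincount(C, minlength=K).astype(float)
        w = rng.dirichlet(hyper.s + counts)

        for k in range(K):
            idx = np.flatnonzero(C == k)
            alpha[k], beta[k], s2e[k], s2x[k] = _draw_component_params(
                rng, k, idx, Y, Xs[k], alpha[k], s2e[k], s2x[k], hyper)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_w[kept] = w
            out_alpha[kept] = alpha
            for k in range(K):
                out_beta[k][kept] = beta[k]
            out_s2x[kept] = s2x
            out_s2e[kept] = s2e
            out_C[kept] = C
            kept += 1

    return GibbsChains(w=out_w[:kept], alpha=out_alpha[:kept],
                       beta=[b[:kept] for b in out_beta],
                       sigma2_x=out_s2x[:kept], sigma2_eps=out_s2e[:kept],
                       C=out_C[:kept], burn_in=burn_in, thin=thin, seed=seed,
                       tissue_ids=[b.tissue_id for b in blocks])


def heritability_posterior(chains: GibbsChains,
                           min_draws: int = 100) -> dict[str, dict[str, float]]:
    """Posterior mean and sd of the subtype heritability per tissue.

    h2_k = m_k s2x_k / (m_k s2x_k + s2e_k) evaluated per retained draw.
    """
    if chains.n_draws < min_draws:
        raise ValueError(
            f"need at least {min_draws} retained draws, have {chains.n_draws}"
        )
    m = chains.m
    genetic = m[None, :] * chains.sigma2_x
    h2 = genetic / (genetic + chains.sigma2_eps)
    return {
        tid: {"mean": float(h2[:, k].mean()), "sd": float(h2[:, k].std(ddof=1))}
        for k, tid in enumerate(chains.tissue_ids)
    }


def _batch_means_se(x: np.ndarray, n_batches: int = 12) -> float:
    """Autocorrelation-robust standard error of the mean via batch means."""
    n = x.size // n_batches
    if n < 1:
        return float(x.std(ddof=1) / np.sqrt(x.size))
    means = x[: n * n_batches].reshape(n_batches, n).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke-style convergence z: compare means of early and late segments.

    Standard errors come from batch means, so autocorrelation within each
    segment does not inflate the statistic.
    """
    chain = np.asarray(chain, dtype=float).ravel()
    n = chain.size
    a = chain[: max(int(first * n), 2)]
    b = chain[-max(int(last * n), 2):]
    se = np.hypot(_batch_means_se(a), _batch_means_se(b))
    return float((a.mean() - b.mean()) / se) if se > 0 else 0.0
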