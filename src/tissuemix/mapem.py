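"""MAP expectation-maximization for the Bayesian mixture of regressions.

Each EM sweep maximizes Q(Theta | Theta^(r)) + log f(Theta), where Q is the
usual complete-data conditional expectation and f is the conjugate prior
(Dirichlet on w, Gaussian on alpha_k and beta_k, inverse-gamma on the
variances).  The M-step updates below all reference iteration-r quantities on
their right-hand sides, so the sweep is computed from a frozen snapshot of
Theta^(r) and swapped in whole (Jacobi style), not sequentially.

Update formulas, for each component k with membership weights
gamma_ik and n_k = sum_i gamma_ik:

    w_k      <- n_k / n
    alpha_k  <- [sum_i gamma_ik (y_i - x_ki' beta_k)] / (n_k + s2e_k / s2a)
    beta_k   <- (sum_i gamma_ik x_ki x_ki' + (s2e_k / s2x_k) I)^-1
                 sum_i gamma_ik (y_i - alpha_k) x_ki
    s2e_k    <- [2 b_eps + sum_i gamma_ik (y_i - mu_ik)^2] / (n_k + 2 a_eps + 1)
    s2x_k    <- (E[beta_k' beta_k] + 2 b_x_k) / (m_k + 2 a_x + 1)

The beta update is the posterior mean of beta_k under its hierarchical
N(0, s2x_k I) prior, so the effect-size variance update uses the matching
posterior second moment,

    E[beta_k' beta_k] = beta_hat' beta_hat + s2e_k tr[(Gram_k + ridge_k I)^-1],

treating beta_k as a latent variable (``sigma2_x_update="em"``, the
default).  The plug-in alternative that drops the trace term
(``sigma2_x_update="plugin"``) is kept for comparison but is unstable: the
plug-in beta'beta under-measures m_k s2x_k by the squared ridge shrinkage
factor, so whenever n_k is not much larger than s2e/s2x the update
contracts s2x geometrically to zero, shrinking beta away with it.

The ridge term s2e/s2x makes the penalized Gram matrix symmetric positive
definite, so beta is obtained from a Cholesky solve, never an explicit
inverse.  The 2b terms in the variance numerators keep every variance
strictly positive at every iteration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg as sla
from scipy.stats import invgamma

from .likelihood import component_means, log_likelihood, responsibilities
from .params import (
    Hyperparams,
    MixtureParams,
    ResponsibilityMatrix,
    TissueBlock,
    TissueParams,
    check_blocks,
)
from .results import MixtureResults

__all__ = ["initialize", "m_step", "fit", "log_prior"]

# Components whose total membership weight falls below this floor are flagged
# as degenerate and their mixing proportion is floored at 1/n.
_NK_FLOOR = 1.0


def initialize(Y: np.ndarray, blocks: list[TissueBlock], hyper: Hyperparams,
               seed: int | None = None) -> MixtureParams:
    """Starting point shared by the MAP-EM and EM engines.

    sigma2_eps_k = 0.95 var(Y); sigma2_x_k = 0.05 var(Y) / m_k; alpha_k = 0;
    w_k = 1/K; beta_k drawn from N(0, sigma2_x_k I) with the given seed.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    check_blocks(blocks)
    K = len(blocks)
    if Y.shape[0] < K:
        raise ValueError("need at least K individuals")
    var_y = float(np.var(Y))
    if var_y == 0.0:
        raise ValueError("constant phenotype: var(Y) = 0")
    rng = np.random.default_rng(seed)
    tissues = []
    for b in blocks:
        s2x = 0.05 * var_y / b.m
        beta0 = rng.normal(0.0, np.sqrt(s2x), size=b.m)
        tissues.append(TissueParams(w=1.0 / K, alpha=0.0, beta=beta0,
                                    sigma2_x=s2x, sigma2_eps=0.95 * var_y))
    return MixtureParams(tissues=tissues, hyper=hyper)


def _weighted_gram(X: np.ndarray, g: np.ndarray) -> np.ndarray:
    A = X * np.sqrt(g)[:, None]
    return A.T @ A


def m_step(Y: np.ndarray, blocks: list[TissueBlock], gamma: ResponsibilityMatrix,
           theta: MixtureParams, hyper: Hyperparams,
           sigma2_x_update: str = "em") -> MixtureParams:
    """One MAP M-step computed from the iteration-r snapshot (Jacobi sweep)."""
    if sigma2_x_update not in ("em", "plugin"):
        raise ValueError("sigma2_x_update must be 'em' or 'plugin'")
    Y = np.asarray(Y, dtype=float).ravel()
    n = Y.shape[0]
    new_tissues = []
    for k, (block, t) in enumerate(zip(blocks, theta.tissues)):
        g = gamma.gamma[:, k]
        n_k = float(g.sum())
        X = block.genotypes
        Xb = X @ t.beta
        mu_r = t.alpha + Xb

        if n_k < _NK_FLOOR:
            warnings.warn(
                f"component {block.tissue_id!r} degenerate (n_k={n_k:.3g}); "
                "mixing proportion floored at 1/n",
                RuntimeWarning, stacklevel=2,
            )
            w_new = 1.0 / n
        else:
            w_new = n_k / n

        denom_a = n_k + t.sigma2_eps / hyper.sigma2_alpha
        alpha_new = float(g @ (Y - Xb)) / denom_a

        ridge = t.sigma2_eps / t.sigma2_x
        G = _weighted_gram(X, g)
        G[np.diag_indices_from(G)] += ridge
        rhs = X.T @ (g * (Y - t.alpha))
        try:
            c, low = sla.cho_factor(G, lower=True, check_finite=False)
            beta_new = sla.cho_solve((c, low), rhs, check_finite=False)
        except sla.LinAlgError as exc:  # pragma: no cover - SPD by construction
            raise RuntimeError(
                f"penalized Gram matrix not SPD for component "
                f"{block.tissue_id!r}: internal fault"
            ) from exc

        s2e_new = (2.0 * hyper.b_eps + float(g @ (Y - mu_r) ** 2)) / (
            n_k + 2.0 * hyper.a_eps + 1.0)
        if sigma2_x_update == "em":
            # E[beta'beta] under the current beta posterior:
            # tr of the posterior covariance s2e (G + ridge I)^-1 via the
            # Cholesky factor already in hand
            inv_l = sla.solve_triangular(c, np.eye(block.m), lower=low,
                                         check_finite=False)
            tr_cov = t.sigma2_eps * float(np.sum(inv_l**2))
            e_btb = float(beta_new @ beta_new) + tr_cov
        else:
            e_btb = float(t.beta @ t.beta)
        s2x_new = (e_btb + 2.0 * hyper.b_x[k]) / (
            block.m + 2.0 * hyper.a_x + 1.0)

        new_tissues.append(TissueParams(w=w_new, alpha=alpha_new, beta=beta_new,
                                        sigma2_x=s2x_new, sigma2_eps=s2e_new))
    # renormalize in case a degenerate component was floored
    wsum = sum(t.w for t in new_tissues)
    if not np.isclose(wsum, 1.0):
        for t in new_tissues:
            t.w /= wsum
    return MixtureParams(tissues=new_tissues, hyper=hyper)


def log_prior(theta: MixtureParams, hyper: Hyperparams) -> float:
    """log f(Theta): Dirichlet(w|s) + sum_k Gaussian/inverse-gamma terms.

    Used by the ascent diagnostics; the MAP-EM objective is
    averaged log-likelihood + log_prior / n.
    """
    from scipy.stats import dirichlet, norm

    w = np.clip(theta.w, 1e-300, None)
    lp = float(dirichlet.logpdf(w / w.sum(), hyper.s))
    for k, t in enumerate(theta.tissues):
        lp += float(norm.logpdf(t.alpha, 0.0, np.sqrt(hyper.sigma2_alpha)))
        lp += float(
            -0.5 * t.m * np.log(2.0 * np.pi * t.sigma2_x)
            - float(t.beta @ t.beta) / (2.0 * t.sigma2_x)
        )
        lp += float(invgamma.logpdf(t.sigma2_x, hyper.a_x, scale=hyper.b_x[k]))
        lp += float(invgamma.logpdf(t.sigma2_eps, hyper.a_eps, scale=hyper.b_eps))
    return lp


def fit(Y: np.ndarray, blocks: list[TissueBlock], hyper: Hyperparams,
        delta: float = 1e-5, max_iter: int = 1000,
        seed: int | None = None,
        sigma2_x_update: str = "em") -> MixtureResults:
    """Run MAP-EM to convergence of the averaged observed-data log-likelihood.

    Alternates the E-step (posterior responsibilities at Theta^(r)) with the
    MAP M-step until the averaged log-likelihood moves by at most ``delta``
    between sweeps, or ``max_iter`` sweeps elapse.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    theta = initialize(Y, blocks, hyper, seed=seed)
    trace = [log_likelihood(Y, blocks, theta, averaged=True)]
    converged = False
    iterations = 0
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always", RuntimeWarning)
        for r in range(max_iter):
            gamma = responsibilities(Y, blocks, theta)
            theta = m_step(Y, blocks, gamma, theta, hyper,
                           sigma2_x_update=sigma2_x_update)
            ll = log_likelihood(Y, blocks, theta, averaged=True)
            if not np.isfinite(ll):
                raise RuntimeError(
                    f"non-finite averaged log-likelihood at iteration {r + 1}"
                )
            trace.append(ll)
            iterations = r + 1
            if abs(trace[-1] - trace[-2]) <= delta:
                converged = True
                break
    caught = [str(w.message) for w in wrec]
    gamma = responsibilities(Y, blocks, theta)
    return MixtureResults(params=theta, gamma=gamma,
                          loglik_trace=np.asarray(trace), iterations=iterations,
                          converged=converged, method="map-em", seed=seed,
                          delta=delta, warnings=sorted(set(caught)))
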