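"""Classical EM for the frequentist version of the mixture of regressions.

Identical E-step and initialization to the MAP engine, but the M-step
maximizes Q(Theta | Theta^(r)) alone — no prior terms:

    w_k     <- n_k / n
    alpha_k <- (1/n_k) sum_i gamma_ik (y_i - x_ki' beta_k)
    beta_k  <- (sum_i gamma_ik x_ki x_ki')^-1 sum_i gamma_ik (y_i - alpha_k) x_ki
    s2e_k   <- (1/n_k) sum_i gamma_ik (y_i - mu_ik)^2

sigma2_x_k is carried unchanged from its initialization: in the frequentist
model it is only a device for drawing the starting beta, not a parameter.
Without a ridge penalty the weighted Gram matrix can be singular, so beta is
solved by weighted least squares through an orthogonal factorization with an
explicit rank check instead of the normal equations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg as sla

from .likelihood import log_likelihood, responsibilities
from .mapem import _NK_FLOOR, initialize
from .params import (
    Hyperparams,
    MixtureParams,
    ResponsibilityMatrix,
    TissueBlock,
    TissueParams,
    default_hyperparameters,
)
from .results import MixtureResults

__all__ = ["m_step_em", "fit_em"]


def m_step_em(Y: np.ndarray, blocks: list[TissueBlock],
              gamma: ResponsibilityMatrix,
              theta: MixtureParams) -> MixtureParams:
    """One maximum-likelihood M-step from the iteration-r snapshot."""
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
                f"component {block.tissue_id!r} near-empty (n_k={n_k:.3g})",
                RuntimeWarning, stacklevel=2,
            )
            w_new = 1.0 / n
            n_k = max(n_k, 1.0 / n)
        else:
            w_new = n_k / n

        alpha_new = float(g @ (Y - Xb)) / n_k

        sq = np.sqrt(g)
        A = X * sq[:, None]
        b = sq * (Y - t.alpha)
        beta_new, _, rank, _ = sla.lstsq(A, b, check_finite=False)
        if rank < block.m:
            raise RuntimeError(
                f"weighted Gram matrix singular for component "
                f"{block.tissue_id!r} (rank {rank} < {block.m}); the "
                "frequentist M-step has no ridge regularizer"
            )
        s2e_new = float(g @ (Y - mu_r) ** 2) / n_k

        new_tissues.append(TissueParams(w=w_new, alpha=alpha_new, beta=beta_new,
                                        sigma2_x=t.sigma2_x, sigma2_eps=s2e_new))
    wsum = sum(t.w for t in new_tissues)
    if not np.isclose(wsum, 1.0):
        for t in new_tissues:
            t.w /= wsum
    return MixtureParams(tissues=new_tissues, hyper=theta.hyper)


def fit_em(Y: np.ndarray, blocks: list[TissueBlock],
           delta: float = 1e-5, max_iter: int = 1000,
           seed: int | None = None,
           hyper: Hyperparams | None = None) -> MixtureResults:
    """Run classical EM to convergence of the averaged log-likelihood.

    ``hyper`` only shapes the initialization draw (and defaults to the 5%/95%
    rule); it never enters the M-step.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    if hyper is None:
        hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
    theta = initialize(Y, blocks, hyper, seed=seed)
    trace = [log_likelihood(Y, blocks, theta, averaged=True)]
    converged = False
    iterations = 0
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always", RuntimeWarning)
        for r in range(max_iter):
            gamma = responsibilities(Y, blocks, theta)
            theta = m_step_em(Y, blocks, gamma, theta)
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
    gamma = responsibilities(Y, blocks, theta)
    return MixtureResults(params=theta, gamma=gamma,
                          loglik_trace=np.asarray(trace), iterations=iterations,
                          converged=converged, method="em", seed=seed,
                          delta=delta,
                          warnings=sorted({str(w.message) for w in wrec}))
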