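"""Mixture likelihood, posterior responsibilities, and threshold classification.

All density work happens in log space with log-sum-exp stabilization: a
phenotype far in one component's tail underflows the plain normal density long
before it stops carrying information about the other component.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .params import (
    UNCLASSIFIED,
    ClassificationReport,
    MixtureParams,
    ResponsibilityMatrix,
    TissueBlock,
    check_blocks,
)

__all__ = ["component_means", "log_likelihood", "responsibilities", "classify"]

_LOG_2PI = np.log(2.0 * np.pi)


def component_means(blocks: list[TissueBlock], theta: MixtureParams) -> np.ndarray:
    """mu[i, k] = alpha_k + x_ki' beta_k, shape n x K."""
    if len(blocks) != theta.K:
        raise ValueError(f"{len(blocks)} blocks for {theta.K} components")
    cols = []
    for block, t in zip(blocks, theta.tissues):
        if t.m != block.m:
            raise ValueError(
                f"tissue {block.tissue_id!r}: beta length {t.m} != m_k {block.m}"
            )
        cols.append(t.alpha + block.genotypes @ t.beta)
    return np.column_stack(cols)


def _log_joint(Y: np.ndarray, blocks: list[TissueBlock],
               theta: MixtureParams) -> np.ndarray:
    """log(w_k) + log phi(y_i | mu_ik, sigma2_eps_k), shape n x K.

    Components with w_k = 0 get -inf rather than a NaN from log(0)*finite.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    mu = component_means(blocks, theta)
    if Y.shape[0] != mu.shape[0]:
        raise ValueError("phenotype length does not match genotype matrices")
    s2 = theta.sigma2_eps
    logphi = -0.5 * (_LOG_2PI + np.log(s2)) - (Y[:, None] - mu) ** 2 / (2.0 * s2)
    with np.errstate(divide="ignore"):
        logw = np.log(theta.w)
    return logw + logphi


def log_likelihood(Y: np.ndarray, blocks: list[TissueBlock],
                   theta: MixtureParams, averaged: bool = False) -> float:
    """Observed-data log-likelihood sum_i log sum_k w_k phi(y_i | mu_ik, s2_ek).

    With ``averaged=True`` the sum is divided by n, the form the EM
    convergence monitor tracks.
    """
    check_blocks(blocks)
    lj = _log_joint(Y, blocks, theta)
    ll = float(logsumexp(lj, axis=1).sum())
    return ll / lj.shape[0] if averaged else ll


def responsibilities(Y: np.ndarray, blocks: list[TissueBlock],
                     theta: MixtureParams) -> ResponsibilityMatrix:
    """Posterior membership probabilities by Bayes' rule.

    gamma_ik = w_k phi(y_i|mu_ik, s2_ek) / sum_t w_t phi(y_i|mu_it, s2_et),
    computed via log-sum-exp.  A row whose every component density is zero
    (all w_k = 0, or non-finite inputs) is an error, never silently
    renormalized.
    """
    check_blocks(blocks)
    lj = _log_joint(Y, blocks, theta)
    norm = logsumexp(lj, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = np.flatnonzero(~np.isfinite(norm))
        raise FloatingPointError(
            f"zero total mixture density for individual(s) {bad[:5].tolist()}"
        )
    gamma = np.exp(lj - norm[:, None])
    return ResponsibilityMatrix(gamma, tissue_ids=[b.tissue_id for b in blocks])


def classify(gamma: ResponsibilityMatrix,
             threshold: float = 0.65) -> ClassificationReport:
    """Assign individual i to tissue k iff gamma_ik > threshold.

    The threshold must exceed 0.5 so that at most one tissue can qualify per
    individual; everyone else remains unclassified.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    ids = gamma.tissue_ids or [f"tissue_{k + 1}" for k in range(gamma.K)]
    best = gamma.gamma.argmax(axis=1)
    passed = gamma.gamma[np.arange(gamma.n), best] > threshold
    labels = np.where(passed, np.asarray(ids, dtype=object)[best], UNCLASSIFIED)
    counts = {tid: int(np.sum(labels == tid)) for tid in ids}
    counts[UNCLASSIFIED] = int(np.sum(labels == UNCLASSIFIED))
    return ClassificationReport(threshold=threshold, labels=labels, counts=counts)
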