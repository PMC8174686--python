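"""Model-object surface for the tissue-specific mixture of regressions.

``TissueMixture`` bundles a phenotype vector with K standardized genotype
blocks and exposes ``fit`` (MAP-EM or EM point estimation, returning a
:class:`~tissuemix.results.MixtureResults`) and ``fit_gibbs`` (posterior
sampling, returning a :class:`GibbsResults` whose headline summary is the
tissue-specific subtype heritability).

The phenotype is taken as given: the model assumes it is already
covariate-adjusted and, ideally, inverse-normal transformed — each mixture
component is a Gaussian linear model — but no transform is applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import em as em_mod
from . import gibbs as gibbs_mod
from . import mapem
from .io import CohortBundle
from .likelihood import log_likelihood, responsibilities
from .params import (
    Hyperparams,
    MixtureParams,
    TissueBlock,
    check_blocks,
    default_hyperparameters,
    standardize_genotypes,
)
from .results import MixtureResults

__all__ = ["TissueMixture", "GibbsResults"]


@dataclass
class GibbsResults:
    """Posterior draws plus derived summaries."""

    chains: gibbs_mod.GibbsChains

    def heritability(self) -> dict[str, dict[str, float]]:
        """Posterior mean and sd of each tissue's subtype heritability."""
        return gibbs_mod.heritability_posterior(self.chains)

    def summary(self) -> str:
        lines = ["Gibbs posterior summary",
                 f"  retained draws: {self.chains.n_draws} "
                 f"(burn-in {self.chains.burn_in}, thin {self.chains.thin})",
                 "",
                 f"  {'tissue':<16}{'h2 mean':>10}{'h2 sd':>10}{'w mean':>10}"]
        h2 = self.heritability()
        wbar = self.chains.w.mean(axis=0)
        for k, tid in enumerate(self.chains.tissue_ids):
            lines.append(f"  {tid:<16}{h2[tid]['mean']:>10.4f}"
                         f"{h2[tid]['sd']:>10.4f}{wbar[k]:>10.4f}")
        return "\n".join(lines)


class TissueMixture:
    """Finite mixture of regressions over tissue-specific eQTL SNP sets.

    Parameters
    ----------
    endog : array-like, length n
        Quantitative phenotype, one value per unrelated individual.
    blocks : list of TissueBlock
        One standardized genotype block per candidate tissue; SNP sets must
        be non-overlapping.
    hyperparams : Hyperparams, optional
        Conjugate prior; defaults to the 5%/95% variance-split rule.
    """

    def __init__(self, endog, blocks: list[TissueBlock],
                 hyperparams: Hyperparams | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        check_blocks(blocks)
        if blocks[0].n != self.endog.shape[0]:
            raise ValueError("phenotype length does not match genotype matrices")
        for b in blocks:
            b.validate_standardized()
        self.blocks = blocks
        var_y = float(np.var(self.endog))
        if var_y == 0:
            raise ValueError("constant phenotype")
        self.hyperparams = hyperparams or default_hyperparameters(
            var_y, [b.m for b in blocks])

    @classmethod
    def from_dosages(cls, endog, dosages: dict[str, np.ndarray],
                     snp_ids: dict[str, list[str]] | None = None,
                     hyperparams: Hyperparams | None = None) -> "TissueMixture":
        """Build from raw dosage matrices; standardizes on the full sample."""
        blocks = []
        for tissue, X in dosages.items():
            ids = (snp_ids[tissue] if snp_ids and tissue in snp_ids
                   else [f"{tissue}_snp{j}" for j in range(X.shape[1])])
            blocks.append(TissueBlock(tissue, ids, standardize_genotypes(X)))
        return cls(endog, blocks, hyperparams)

    @classmethod
    def from_cohort(cls, bundle: CohortBundle,
                    hyperparams: Hyperparams | None = None) -> "TissueMixture":
        model = cls(bundle.phenotype, bundle.blocks, hyperparams)
        model.individual_ids = bundle.individual_ids
        return model

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    def loglike(self, params: MixtureParams, averaged: bool = False) -> float:
        return log_likelihood(self.endog, self.blocks, params, averaged=averaged)

    def responsibilities(self, params: MixtureParams):
        return responsibilities(self.endog, self.blocks, params)

    def fit(self, method: str = "map-em", delta: float = 1e-5,
            max_iter: int = 1000, seed: int | None = None) -> MixtureResults:
        """Point estimation by MAP-EM (default) or classical EM."""
        if method == "map-em":
            return mapem.fit(self.endog, self.blocks, self.hyperparams,
                             delta=delta, max_iter=max_iter, seed=seed)
        if method == "em":
            return em_mod.fit_em(self.endog, self.blocks, delta=delta,
                                 max_iter=max_iter, seed=seed,
                                 hyper=self.hyperparams)
        raise ValueError(f"unknown method {method!r}; use 'map-em' or 'em'")

    def fit_gibbs(self, iters: int = 5000, burn_in: int = 2000, thin: int = 1,
                  seed: int | None = None) -> GibbsResults:
        """Posterior sampling; use for subtype-heritability estimation."""
        chains = gibbs_mod.gibbs_fit(self.endog, self.blocks, self.hyperparams,
                                     iters=iters, burn_in=burn_in, thin=thin,
                                     seed=seed)
        return GibbsResults(chains=chains)
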