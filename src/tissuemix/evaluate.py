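"""Simulation-study metrics and experiment drivers.

AUC measures how well the tissue-1 posterior separates the two true
components; the gold-standard comparator evaluates the same posterior at the
*true* generating parameters, an upper bound on what any estimate of the
model can achieve.  TDR (true discovery rate) and POD (proportion of
discovery) summarize threshold classification: TDR is the fraction of
threshold-classified individuals assigned their true tissue, POD the
fraction of all individuals classified at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import em as em_mod
from . import mapem
from .likelihood import classify, responsibilities
from .params import Hyperparams, default_hyperparameters
from .results import MixtureResults
from .simulate import SimConfig, simulate_dataset

__all__ = [
    "auc",
    "tdr_pod",
    "ScenarioResult",
    "run_scenario",
    "irrelevant_tissue_experiment",
    "permutation_experiment",
    "eqtl_shuffle_experiment",
    "DEFAULT_THRESHOLDS",
]

# the threshold grid swept in the study: 55%, 60%, ..., 95%
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.55, 0.951, 0.05), 2))


def auc(true_component: np.ndarray, gamma_column: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of the tissue-1 posterior vs truth.

    ``true_component`` holds 0-based component labels; component 0 is the
    positive class and ``gamma_column`` its posterior probability.  Ties are
    mid-ranked.
    """
    truth = np.asarray(true_component)
    if np.unique(truth).size < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    return float(roc_auc_score((truth == 0).astype(int), gamma_column))


def tdr_pod(true_component: np.ndarray, gamma, thresholds=DEFAULT_THRESHOLDS
            ) -> pd.DataFrame:
    """Per-threshold TDR and POD table.

    TDR is reported as missing (NaN) at thresholds where nobody is
    classified — never as 0, which would conflate abstention with error.
    """
    truth = np.asarray(true_component)
    rows = []
    ids = gamma.tissue_ids or [f"tissue_{k + 1}" for k in range(gamma.K)]
    for t in thresholds:
        rep = classify(gamma, threshold=float(t))
        assigned = rep.labels != "unclassified"
        n_assigned = int(assigned.sum())
        if n_assigned == 0:
            tdr = np.nan
        else:
            predicted = np.array(
                [ids.index(l) if l in ids else -1 for l in rep.labels[assigned]]
            )
            tdr = float(np.mean(predicted == truth[assigned]))
        rows.append({"threshold": float(t), "tdr": tdr,
                     "pod": n_assigned / truth.size, "n_assigned": n_assigned})
    return pd.DataFrame(rows)


@dataclass
class ScenarioResult:
    """Replicate-level metrics for one simulation scenario."""

    config: SimConfig
    method: str
    aucs: list[float] = field(default_factory=list)
    gold_aucs: list[float] = field(default_factory=list)
    tdr_pod_tables: list[pd.DataFrame] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def mean_gold_auc(self) -> float:
        return float(np.mean(self.gold_aucs))

    @property
    def auc_deficit(self) -> float:
        """Mean AUC lost relative to the true-parameter classifier."""
        return self.mean_gold_auc - self.mean_auc

    def mean_tdr_pod(self) -> pd.DataFrame:
        stacked = pd.concat(self.tdr_pod_tables)
        return stacked.groupby("threshold", as_index=False)[["tdr", "pod"]].mean()


def _fit(method: str, Y, blocks, hyper: Hyperparams, seed, **kw) -> MixtureResults:
    if method == "map-em":
        return mapem.fit(Y, blocks, hyper, seed=seed, **kw)
    if method == "em":
        return em_mod.fit_em(Y, blocks, seed=seed, hyper=hyper, **kw)
    raise ValueError(f"unknown method {method!r}")


def run_scenario(config: SimConfig, replicates: int = 50, method: str = "map-em",
                 seed: int | None = None, thresholds=DEFAULT_THRESHOLDS,
                 **fit_kw) -> ScenarioResult:
    """Simulate-fit-score cycle for one scenario.

    Per replicate: draw a dataset, fit the requested engine, compute AUC of
    the tissue-1 posterior against truth, the gold-standard AUC at the true
    parameters, and the TDR/POD sweep.  A replicate whose fit fails is
    recorded and skipped, not fatal to the grid.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    ss = np.random.SeedSequence(seed)
    out = ScenarioResult(config=config, method=method)
    for child in ss.spawn(replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = SimConfig(**{**config.to_dict(), "seed": rep_seed,
                           "m": tuple(config.m), "w": tuple(config.w),
                           "h2": tuple(config.h2),
                           "alpha": tuple(config.alpha),
                           "beta_mean": tuple(config.beta_mean),
                           "sigma2_y": tuple(config.sigma2_y),
                           "maf_range": tuple(config.maf_range)})
        try:
            Y, truth, blocks = simulate_dataset(cfg)
            hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
            res = _fit(method, Y, blocks, hyper, rep_seed, **fit_kw)
            gold = responsibilities(Y, blocks, truth.true_params())
            out.aucs.append(auc(truth.C, res.gamma.gamma[:, 0]))
            out.gold_aucs.append(auc(truth.C, gold.gamma[:, 0]))
            out.tdr_pod_tables.append(tdr_pod(truth.C, res.gamma, thresholds))
            out.seeds.append(rep_seed)
        except (RuntimeError, FloatingPointError) as exc:
            out.failures.append(f"seed {rep_seed}: {exc}")
    return out


def irrelevant_tissue_experiment(n: int = 20_000, m: tuple[int, int] = (1000, 1000),
                                 h2_relevant: float = 0.20,
                                 sigma2_y: float = 10.0,
                                 replicates: int = 1,
                                 threshold: float = 0.65,
                                 thresholds=DEFAULT_THRESHOLDS,
                                 seed: int | None = None,
                                 **fit_kw) -> pd.DataFrame:
    """Include a phenotype-irrelevant SNP set and measure misclassification.

    All n individuals truly belong to tissue 1 (its SNPs explain
    ``h2_relevant`` of the trait variance); tissue 2's SNPs contribute
    nothing.  Returns a per-replicate, per-threshold table of the percent
    correctly assigned to tissue 1 and the percent misassigned to tissue 2;
    the requested headline ``threshold`` is guaranteed to appear in the sweep.
    """
    sweep = sorted(set(float(t) for t in thresholds) | {float(threshold)})
    ss = np.random.SeedSequence(seed)
    rows = []
    for r, child in enumerate(ss.spawn(replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = SimConfig(n=n, m=m, w=(1.0, 0.0), h2=(h2_relevant, 0.0),
                        sigma2_y=sigma2_y, seed=rep_seed)
        Y, truth, blocks = simulate_dataset(cfg)
        hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
        res = mapem.fit(Y, blocks, hyper, seed=rep_seed, **fit_kw)
        g = res.gamma.gamma
        for t in sweep:
            rows.append({
                "replicate": r, "threshold": t,
                "pct_correct": 100.0 * float(np.mean(g[:, 0] > t)),
                "pct_misclassified": 100.0 * float(np.mean(g[:, 1] > t)),
                "seed": rep_seed,
            })
    return pd.DataFrame(rows)


def permutation_experiment(Y, blocks, hyper: Hyperparams | None = None,
                           n_perm: int = 500, threshold: float = 0.65,
                           seed: int | None = None, **fit_kw) -> dict:
    """Phenotype-permutation null: shuffle Y, refit, count classified.

    Breaking the genotype-phenotype link should collapse the number of
    threshold-classified individuals relative to the unpermuted fit.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    if hyper is None:
        hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_perm):
        perm = rng.permutation(Y.size)
        fit_seed = int(rng.integers(2**31))
        res = mapem.fit(Y[perm], blocks, hyper, seed=fit_seed, **fit_kw)
        counts.append(res.classify(threshold).n_classified)
    counts = np.asarray(counts)
    return {"counts": counts, "mean": float(counts.mean()),
            "sd": float(counts.std(ddof=1)) if n_perm > 1 else 0.0,
            "threshold": threshold}


def eqtl_shuffle_experiment(Y, blocks, trait_table: pd.DataFrame,
                            n_swap: int | None = None, n_shuffles: int = 500,
                            threshold: float = 0.65, seed: int | None = None,
                            **fit_kw) -> pd.DataFrame:
    """Swap SNPs between the two tissue sets to build artificial tissues.

    Per shuffle, ``n_swap`` SNPs (default: half the smaller set) are
    exchanged between the two SNP sets — a bijection, so the sets stay
    non-overlapping — the mixture is refit, individuals are classified at
    ``threshold``, and each supplied trait's mean is computed within each
    artificial tissue group.  Returns the per-shuffle group trait means; if
    tissue-specific genetics drives a trait's group mean, the artificial
    groups' means should regress toward the population mean.
    """
    if len(blocks) != 2:
        raise ValueError("the SNP-shuffle experiment is defined for two tissues")
    Y = np.asarray(Y, dtype=float).ravel()
    if n_swap is None:
        n_swap = min(blocks[0].m, blocks[1].m) // 2
    if n_swap > min(blocks[0].m, blocks[1].m):
        raise ValueError("n_swap exceeds the smaller SNP set")
    rng = np.random.default_rng(seed)
    hyper = default_hyperparameters(float(np.var(Y)), [b.m for b in blocks])
    rows = []
    from .params import TissueBlock

    for s in range(n_shuffles):
        # fit seed drawn before the swap indices so that runs with different
        # n_swap share fit initializations shuffle-for-shuffle
        fit_seed = int(rng.integers(2**31))
        if n_swap == 0:
            shuffled = blocks
        else:
            i1 = rng.choice(blocks[0].m, size=n_swap, replace=False)
            i2 = rng.choice(blocks[1].m, size=n_swap, replace=False)
            g1 = blocks[0].genotypes.copy()
            g2 = blocks[1].genotypes.copy()
            ids1 = list(blocks[0].snp_ids)
            ids2 = list(blocks[1].snp_ids)
            g1[:, i1], g2[:, i2] = g2[:, i2], g1[:, i1].copy()
            for a, b in zip(i1, i2):
                ids1[a], ids2[b] = ids2[b], ids1[a]
            shuffled = [
                TissueBlock(blocks[0].tissue_id, ids1, g1),
                TissueBlock(blocks[1].tissue_id, ids2, g2),
            ]
        res = mapem.fit(Y, shuffled, hyper, seed=fit_seed, **fit_kw)
        labels = res.classify(threshold).labels
        for tid in (blocks[0].tissue_id, blocks[1].tissue_id):
            mask = labels == tid
            for trait in trait_table.columns:
                vals = trait_table[trait].to_numpy(dtype=float)[mask]
                rows.append({
                    "shuffle": s, "tissue": tid, "trait": trait,
                    "group_size": int(mask.sum()),
                    "group_mean": float(np.nanmean(vals)) if mask.any() else np.nan,
                })
    return pd.DataFrame(rows)
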