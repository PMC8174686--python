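"""Genotype and phenotype simulator for the tissue-specific mixture model.

Genotypes emulate LD-pruned biallelic SNPs: per SNP a minor-allele frequency
is drawn uniformly from ``maf_range`` and dosages are binomial(2, p) draws,
independent across SNPs and individuals — Hardy-Weinberg equilibrium by
construction, and no residual LD, mimicking a SNP panel pruned at r^2 < 0.25.
An optional autoregressive mode introduces adjacent-SNP correlation for
robustness checks.

Phenotypes follow the study design the fitting engines assume: each
individual belongs to one tissue component (assignment is deterministic by
quota: the first floor(n w_1) individuals to tissue 1, and so on), per-SNP
effects are drawn as beta_kj ~ N(beta_mean_k, h2_k sigma2_y_k / m_k), and
noise is N(0, (1 - h2_k) sigma2_y_k).  Two different standardizations are
deliberate and load-bearing: the genotype columns that *generate* a
subgroup's phenotype are standardized within that subgroup only, while the
blocks returned for *fitting* are re-standardized on all n individuals,
because the tissue of interest is unknown at fitting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .params import MixtureParams, TissueBlock, TissueParams, standardize_genotypes

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "ld_prune",
    "simulate_phenotypes",
    "simulate_dataset",
    "simulate_shared_effects",
    "default_scenario_grid",
]

SHARED = -1  # truth label for individuals with effects from every tissue


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults are the simulation study's baseline: total trait variance 10 per
    subtype, zero baseline means, zero-mean effect sizes, MAF uniform on
    [0.01, 0.5].
    """

    n: int = 10_000
    m: tuple[int, ...] = (1000, 1000)
    w: tuple[float, ...] = (0.5, 0.5)
    h2: tuple[float, ...] = (0.1, 0.1)
    alpha: tuple[float, ...] = (0.0, 0.0)
    beta_mean: tuple[float, ...] | None = None
    sigma2_y: tuple[float, ...] | float = 10.0
    maf_range: tuple[float, float] = (0.01, 0.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        K = len(self.m)
        if self.beta_mean is None:
            self.beta_mean = tuple(0.0 for _ in range(K))
        if np.isscalar(self.sigma2_y):
            self.sigma2_y = tuple(float(self.sigma2_y) for _ in range(K))
        if not (len(self.w) == len(self.h2) == len(self.alpha)
                == len(self.beta_mean) == len(self.sigma2_y) == K):
            raise ValueError("per-tissue parameter tuples disagree on K")
        if not np.isclose(sum(self.w), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        if any(not 0.0 <= h <= 1.0 for h in self.h2):
            raise ValueError("subtype heritabilities must lie in [0, 1]")
        if any(s <= 0 for s in self.sigma2_y):
            raise ValueError("sigma2_y must be strictly positive")

    @property
    def K(self) -> int:
        return len(self.m)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "m": list(self.m), "w": list(self.w),
            "h2": list(self.h2), "alpha": list(self.alpha),
            "beta_mean": list(self.beta_mean),
            "sigma2_y": list(self.sigma2_y),
            "maf_range": list(self.maf_range), "seed": self.seed,
        }


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset.

    ``C`` holds the true component per individual (0-based; ``SHARED`` marks
    individuals generated with effects from every tissue).  ``beta`` are the
    true per-tissue effect vectors on the generating (subgroup-standardized)
    genotype scale.
    """

    C: np.ndarray
    beta: list[np.ndarray]
    config: SimConfig
    groups: np.ndarray = field(default=None)

    def true_params(self) -> MixtureParams:
        """Generating parameters as a MixtureParams, for the gold-standard
        classifier (responsibilities evaluated at the true parameters)."""
        cfg = self.config
        tissues = [
            TissueParams(
                w=cfg.w[k], alpha=cfg.alpha[k], beta=self.beta[k],
                sigma2_x=max(cfg.h2[k] * cfg.sigma2_y[k] / cfg.m[k], 1e-12),
                sigma2_eps=max((1.0 - cfg.h2[k]) * cfg.sigma2_y[k], 1e-12),
            )
            for k in range(cfg.K)
        ]
        return MixtureParams(tissues=tissues)


def simulate_genotypes(n: int, m: int, maf_range: tuple[float, float] = (0.01, 0.5),
                       seed=None, rho: float = 0.0):
    """Draw an n x m raw dosage matrix in {0,1,2} plus the per-SNP MAFs.

    With ``rho > 0`` adjacent SNPs are correlated through a latent AR(1)
    Gaussian per haplotype (an optional LD mode); the default is independent
    SNPs.  Columns that come out monomorphic are redrawn.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be at least 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mafs = rng.uniform(lo, hi, size=m)
    if rho == 0.0:
        dosages = rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int8)
    else:
        if not -1.0 < rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        thresh = norm.ppf(mafs)
        dosages = np.zeros((n, m), dtype=np.int8)
        for _ in range(2):  # two haplotypes per individual
            z = np.empty((n, m))
            z[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, m - 1)) * np.sqrt(1 - rho**2)
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
            dosages += (z < thresh[None, :]).astype(np.int8)
    # redraw monomorphic columns (possible at small n or extreme MAF)
    for _ in range(100):
        mono = np.flatnonzero(dosages.std(axis=0) == 0)
        if mono.size == 0:
            break
        mafs[mono] = rng.uniform(lo, hi, size=mono.size)
        dosages[:, mono] = rng.binomial(2, mafs[None, mono], size=(n, mono.size))
    else:
        raise RuntimeError("could not draw polymorphic columns; widen maf_range")
    return dosages, mafs


def ld_prune(dosages: np.ndarray, r2_max: float = 0.25) -> np.ndarray:
    """Greedy consecutive-pair LD pruning.

    Scans left to right in the given column order (the order stands in for
    genomic position); a SNP is dropped when its squared Pearson correlation
    with the most recently retained SNP is >= ``r2_max``.  Returns the
    retained column indices in order.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two SNPs to prune")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column(s); filter monomorphic SNPs first")
    keep = [0]
    for j in range(1, X.shape[1]):
        r = np.corrcoef(X[:, keep[-1]], X[:, j])[0, 1]
        if r * r < r2_max:
            keep.append(j)
    return np.asarray(keep, dtype=int)


def _quota_assignments(n: int, w: tuple[float, ...]) -> np.ndarray:
    """Deterministic quota assignment: first floor(n w_1) individuals to
    component 0, the next floor(n w_2) to component 1, remainder to the last."""
    counts = np.floor(np.asarray(w) * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    return np.repeat(np.arange(len(w)), counts)


def _subgroup_standardize(X: np.ndarray, rows: np.ndarray) -> np.ndarray:
    sub = X[rows].astype(float)
    try:
        return standardize_genotypes(sub)
    except ValueError as exc:
        raise ValueError(
            "a genotype column is monomorphic within an assigned subgroup; "
            "the subgroup is too small to standardize"
        ) from exc


def simulate_phenotypes(config: SimConfig, dosages: list[np.ndarray],
                        rng: np.random.Generator | None = None):
    """Generate (Y, SimTruth, fitting blocks) from raw per-tissue dosages.

    The generating genotypes are standardized within each assigned subgroup;
    the returned TissueBlocks are standardized on the full sample.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(dosages) != config.K:
        raise ValueError("one dosage matrix per tissue required")
    n = config.n
    for X in dosages:
        if X.shape[0] != n:
            raise ValueError("dosage matrices must have n rows")
    C = _quota_assignments(n, config.w)
    Y = np.empty(n)
    beta_true: list[np.ndarray] = []
    for k in range(config.K):
        m_k = config.m[k]
        if dosages[k].shape[1] != m_k:
            raise ValueError(f"tissue {k}: expected {m_k} SNPs")
        sd_beta = np.sqrt(config.h2[k] * config.sigma2_y[k] / m_k)
        beta_k = rng.normal(config.beta_mean[k], sd_beta, size=m_k)
        beta_true.append(beta_k)
        rows = np.flatnonzero(C == k)
        if rows.size == 0:  # tissue carries no individuals (e.g. w_k = 0)
            continue
        x_sub = _subgroup_standardize(dosages[k], rows)
        eps = rng.normal(0.0, np.sqrt((1.0 - config.h2[k]) * config.sigma2_y[k]),
                         size=rows.size)
        Y[rows] = config.alpha[k] + x_sub @ beta_k + eps
    blocks = [
        TissueBlock(
            tissue_id=f"tissue_{k + 1}",
            snp_ids=[f"t{k + 1}_snp{j}" for j in range(config.m[k])],
            genotypes=standardize_genotypes(dosages[k]),
        )
        for k in range(config.K)
    ]
    truth = SimTruth(C=C, beta=beta_true, config=config, groups=None)
    return Y, truth, blocks


def simulate_dataset(config: SimConfig):
    """Full pipeline: draw genotypes, then phenotypes; one seed drives all."""
    rng = np.random.default_rng(config.seed)
    dosages = [
        simulate_genotypes(config.n, m_k, config.maf_range, seed=rng)[0]
        for m_k in config.m
    ]
    return simulate_phenotypes(config, dosages, rng=rng)


def simulate_shared_effects(n_per_group: int, m: tuple[int, int] = (1000, 1000),
                            h2: float = 0.2, sigma2_y: float = 10.0,
                            alpha: tuple[float, float] = (0.0, 0.0),
                            maf_range: tuple[float, float] = (0.01, 0.5),
                            shared_split: float = 0.5,
                            seed: int | None = None):
    """Three-group design: tissue-1-only, both-tissues, tissue-2-only.

    The middle group's phenotype receives genetic effects from both SNP sets;
    its genetic variance h2 sigma2_y is split between the two components in
    proportion ``shared_split`` : (1 - shared_split) (default equal halves)
    so the total subtype variance stays at sigma2_y.
    """
    if not 0.0 < shared_split < 1.0:
        raise ValueError("shared_split must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = 3 * n_per_group
    config = SimConfig(n=n, m=m, w=(0.5, 0.5), h2=(h2, h2), alpha=alpha,
                       sigma2_y=sigma2_y, maf_range=maf_range, seed=seed)
    dosages = [simulate_genotypes(n, m_k, maf_range, seed=rng)[0] for m_k in m]
    groups = np.repeat(np.array(["tissue_1", "both", "tissue_2"]), n_per_group)
    C = np.repeat(np.array([0, SHARED, 1]), n_per_group)
    beta_true = [
        rng.normal(0.0, np.sqrt(h2 * sigma2_y / m_k), size=m_k) for m_k in m
    ]
    Y = np.empty(n)
    noise_sd = np.sqrt((1.0 - h2) * sigma2_y)
    for gname, k in (("tissue_1", 0), ("tissue_2", 1)):
        rows = np.flatnonzero(groups == gname)
        x_sub = _subgroup_standardize(dosages[k], rows)
        Y[rows] = (alpha[k] + x_sub @ beta_true[k]
                   + rng.normal(0.0, noise_sd, size=rows.size))
    rows = np.flatnonzero(groups == "both")
    scale = (np.sqrt(shared_split), np.sqrt(1.0 - shared_split))
    g_both = np.zeros(rows.size)
    for k in range(2):
        x_sub = _subgroup_standardize(dosages[k], rows)
        g_both += scale[k] * (x_sub @ beta_true[k])
    alpha_both = 0.5 * (alpha[0] + alpha[1])
    Y[rows] = alpha_both + g_both + rng.normal(0.0, noise_sd, size=rows.size)
    blocks = [
        TissueBlock(
            tissue_id=f"tissue_{k + 1}",
            snp_ids=[f"t{k + 1}_snp{j}" for j in range(m[k])],
            genotypes=standardize_genotypes(dosages[k]),
        )
        for k in range(2)
    ]
    truth = SimTruth(C=C, beta=beta_true, config=config, groups=groups)
    return Y, truth, blocks


def default_scenario_grid() -> list[SimConfig]:
    """The full factorial scenario grid of the simulation study.

    sigma2_y = 10, alpha = (0, 0), w_k in {1/2, 1/3}, h2_k in
    {10%..50%} plus the extreme 0% and 90% anchors, m_k in {1000, 1500},
    n in {40000, 100000}.
    """
    grid: list[SimConfig] = []
    h2_vals = [0.1, 0.2, 0.3, 0.4, 0.5]
    for n in (40_000, 100_000):
        for m1 in (1000, 1500):
            for m2 in (1000, 1500):
                for w1 in (0.5, 1.0 / 3.0):
                    w = (w1, 1.0 - w1)
                    for h1 in h2_vals:
                        for h2_ in h2_vals:
                            grid.append(SimConfig(n=n, m=(m1, m2), w=w,
                                                  h2=(h1, h2_), sigma2_y=10.0))
                    for h_extreme in (0.0, 0.9):
                        grid.append(SimConfig(n=n, m=(m1, m2), w=w,
                                              h2=(h_extreme, h_extreme),
                                              sigma2_y=10.0))
    return grid
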