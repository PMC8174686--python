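"""Core parameter containers for the tissue-specific mixture of regressions.

The model assumes that the quantitative phenotype ``y_i`` of each unrelated
individual arises from exactly one of ``K`` tissue-specific linear components,

    y_i = alpha_k + x_ki' beta_k + eps_ki,   eps_ki ~ N(0, sigma2_eps_k),

where ``x_ki`` holds the individual's standardized genotype dosages at the
``m_k`` eQTL SNPs specific to tissue ``k``.  The latent component indicator
``C_i = k`` has prior probability ``w_k``.  Because each component regresses on
a distinct, non-overlapping SNP set, the mixture is identifiable without any
label-switching canonicalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueBlock",
    "TissueParams",
    "Hyperparams",
    "MixtureParams",
    "ResponsibilityMatrix",
    "ClassificationReport",
    "default_hyperparameters",
    "standardize_genotypes",
]


def standardize_genotypes(dosages: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Column-standardize a dosage matrix to mean 0, variance 1.

    Raises ``ValueError`` on monomorphic (zero-variance) columns rather than
    silently producing NaN.
    """
    dosages = np.asarray(dosages, dtype=float)
    mu = dosages.mean(axis=0)
    sd = dosages.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"monomorphic genotype column(s) at index {bad.tolist()}")
    return (dosages - mu) / sd


@dataclass
class TissueBlock:
    """One tissue's eQTL SNP set: identifiers plus an n x m_k genotype matrix.

    ``genotypes`` is expected to be column-standardized (full-sample mean 0,
    variance 1) before fitting; ``validate`` checks this to a loose tolerance.
    """

    tissue_id: str
    snp_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.snp_ids = list(self.snp_ids)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (individuals x SNPs)")
        if len(self.snp_ids) != self.genotypes.shape[1]:
            raise ValueError(
                f"tissue {self.tissue_id!r}: {len(self.snp_ids)} SNP ids for "
                f"{self.genotypes.shape[1]} genotype columns"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"tissue {self.tissue_id!r}: duplicate SNP ids")
        if self.m == 0:
            raise ValueError(f"tissue {self.tissue_id!r}: empty SNP set")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def validate_standardized(self, atol: float = 1e-6) -> None:
        mu = self.genotypes.mean(axis=0)
        var = self.genotypes.var(axis=0)
        if not (np.allclose(mu, 0.0, atol=atol) and np.allclose(var, 1.0, atol=1e-3)):
            raise ValueError(
                f"tissue {self.tissue_id!r}: genotype columns are not standardized"
            )


def check_blocks(blocks: list[TissueBlock]) -> None:
    """Validate a list of tissue blocks: consistent n, non-overlapping SNP sets."""
    if not blocks:
        raise ValueError("at least one tissue block required")
    n = blocks[0].n
    seen: dict[str, str] = {}
    for b in blocks:
        if b.n != n:
            raise ValueError("tissue blocks disagree on the number of individuals")
        for s in b.snp_ids:
            if s in seen:
                raise ValueError(
                    f"SNP {s!r} appears in tissues {seen[s]!r} and {b.tissue_id!r}; "
                    "tissue-specific SNP sets must be non-overlapping"
                )
            seen[s] = b.tissue_id


@dataclass
class TissueParams:
    """theta_k = (w_k, alpha_k, beta_k, sigma2_x_k, sigma2_eps_k)."""

    w: float
    alpha: float
    beta: np.ndarray
    sigma2_x: float
    sigma2_eps: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.sigma2_x <= 0 or self.sigma2_eps <= 0:
            raise ValueError("variance parameters must be strictly positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixing proportion must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.beta.shape[0]


@dataclass
class Hyperparams:
    """Conjugate prior settings.

    ``a_x, b_x`` — inverse-gamma shape/scale for each tissue's effect-size
    variance sigma2_x_k (``b_x`` is per-tissue because its prior mean scales
    as 1/m_k); ``a_eps, b_eps`` — inverse-gamma shape/scale for the residual
    variances; ``sigma2_alpha`` — Gaussian prior variance of the baseline
    means; ``s`` — Dirichlet concentration for the mixing proportions.
    """

    a_x: float
    b_x: np.ndarray  # length K
    a_eps: float
    b_eps: float
    sigma2_alpha: float = 1.0
    s: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self) -> None:
        self.b_x = np.atleast_1d(np.asarray(self.b_x, dtype=float))
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        for name in ("a_x", "a_eps", "b_eps", "sigma2_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.b_x <= 0) or np.any(self.s <= 0):
            raise ValueError("b_x and s entries must be strictly positive")


def default_hyperparameters(
    var_y: float,
    m: tuple[int, ...] | list[int] | np.ndarray,
    prior_genetic_fraction: float = 0.05,
    shape: float = 3.0,
) -> Hyperparams:
    """Build the default conjugate prior from the phenotype variance.

    The inverse-gamma scales are chosen so that, in prior expectation, a
    fraction ``prior_genetic_fraction`` (default 5%) of the phenotypic variance
    of each tissue-specific subtype is explained by that tissue's m_k SNPs and
    the rest stays residual: E[sigma2_x_k] = f * var_y / m_k and
    E[sigma2_eps_k] = (1 - f) * var_y.  With IG(a, b), the mean is b / (a - 1),
    so b = (shape - 1) * target mean; the shape must exceed 1 for the mean to
    exist.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    if var_y <= 0:
        raise ValueError("var_y must be strictly positive")
    if shape <= 1:
        raise ValueError("inverse-gamma shape must exceed 1 (prior mean undefined)")
    if not 0 < prior_genetic_fraction < 1:
        raise ValueError("prior_genetic_fraction must lie in (0, 1)")
    if np.any(m < 1):
        raise ValueError("every tissue must contribute at least one SNP")
    K = m.shape[0]
    b_x = (shape - 1.0) * prior_genetic_fraction * var_y / m
    b_eps = (shape - 1.0) * (1.0 - prior_genetic_fraction) * var_y
    return Hyperparams(a_x=shape, b_x=b_x, a_eps=shape, b_eps=b_eps,
                       sigma2_alpha=1.0, s=np.ones(K))


@dataclass
class MixtureParams:
    """Theta = (theta_1, ..., theta_K) plus the prior settings used to fit."""

    tissues: list[TissueParams]
    hyper: Hyperparams | None = None

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError("at least one component required")
        w = self.w
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError(f"mixing proportions sum to {w.sum()}, not 1")

    @property
    def K(self) -> int:
        return len(self.tissues)

    @property
    def w(self) -> np.ndarray:
        return np.array([t.w for t in self.tissues])

    @property
    def alpha(self) -> np.ndarray:
        return np.array([t.alpha for t in self.tissues])

    @property
    def sigma2_eps(self) -> np.ndarray:
        return np.array([t.sigma2_eps for t in self.tissues])

    @property
    def sigma2_x(self) -> np.ndarray:
        return np.array([t.sigma2_x for t in self.tissues])

    def to_dict(self, snp_ids: list[list[str]] | None = None) -> dict:
        """JSON-serializable parameter dump (beta keyed by SNP id if given)."""
        out: dict = {"K": self.K, "tissues": []}
        for k, t in enumerate(self.tissues):
            beta = t.beta.tolist()
            if snp_ids is not None:
                beta = dict(zip(snp_ids[k], beta))
            out["tissues"].append(
                {"w": t.w, "alpha": t.alpha, "beta": beta,
                 "sigma2_x": t.sigma2_x, "sigma2_eps": t.sigma2_eps}
            )
        if self.hyper is not None:
            h = self.hyper
            out["hyperparameters"] = {
                "a_x": h.a_x, "b_x": h.b_x.tolist(), "a_eps": h.a_eps,
                "b_eps": h.b_eps, "sigma2_alpha": h.sigma2_alpha,
                "s": h.s.tolist(),
            }
        return out


@dataclass
class ResponsibilityMatrix:
    """Posterior tissue-membership probabilities Gamma = {gamma_ik}, n x K.

    ``gamma[i, k]`` is the posterior probability that individual i's genetic
    contribution to the trait is mediated through tissue k; rows live on the
    probability simplex.  ``n_k = gamma.sum(axis=0)`` are the total membership
    weights.
    """

    gamma: np.ndarray
    tissue_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 2:
            raise ValueError("gamma must be n x K")
        if np.any(self.gamma < -1e-12) or np.any(self.gamma > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        rows = self.gamma.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("responsibility rows must sum to 1")

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    @property
    def K(self) -> int:
        return self.gamma.shape[1]

    @property
    def n_k(self) -> np.ndarray:
        return self.gamma.sum(axis=0)


UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationReport:
    """Hard tissue assignments at a posterior-probability threshold.

    Individual i is assigned tissue k iff gamma_ik > threshold; thresholds
    above 0.5 guarantee at most one tissue can qualify, and individuals whose
    maximum posterior does not clear the bar stay unclassified (the posterior
    near 50% means no tissue is prioritized).
    """

    threshold: float
    labels: np.ndarray  # object array of tissue ids / "unclassified"
    counts: dict[str, int]

    @property
    def n_classified(self) -> int:
        return int(sum(v for k, v in self.counts.items() if k != UNCLASSIFIED))
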