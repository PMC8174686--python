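# tissuemix

Per-individual tissue-of-interest classification for complex traits, from
genotypes at tissue-specific eQTL SNP sets.

Complex traits such as BMI are mediated through several tissues, but not
necessarily through the same tissue in every person.  `tissuemix` takes a
quantitative phenotype for `n` unrelated individuals together with `K`
non-overlapping SNP sets — each set the eQTLs of genes specifically
expressed in one candidate tissue — and estimates, for every individual,
the posterior probability that their genetic predisposition runs through
each tissue.  It is aimed at statistical geneticists working with
biobank-scale cohorts and GTEx-style eQTL resources.

## The model

A finite mixture of regressions with distinct predictor sets per component:

    y_i | C_i = k  ~  N(alpha_k + x_ki' beta_k,  sigma2_eps_k),
    P(C_i = k) = w_k,       k = 1..K,

where `x_ki` are individual `i`'s standardized dosages at tissue `k`'s
`m_k` eQTL SNPs and `C_i` is the latent tissue of interest.  Priors:
`w ~ Dirichlet(1)`, `alpha_k ~ N(0,1)`, `beta_k ~ N(0, sigma2_x_k I)`, and
inverse-gamma priors on the variances fixed so that each tissue's SNPs
explain 5% of the subtype variance in prior expectation.  Inference is by
MAP expectation-maximization (a classical EM engine and a Gibbs sampler —
the instrument for subtype-heritability posteriors
`h2_k = m_k s2x_k / (m_k s2x_k + s2e_k)` — are included).  The main output
is the responsibility matrix `gamma_ik = P(C_i = k | y_i, Theta)`;
individuals whose top posterior clears a threshold (default 65%) are
classified, the rest stay unclassified.  See `docs/methods.md` for the full
treatment.

## Worked example

```python
import numpy as np
from tissuemix import SimConfig, TissueMixture, auc, simulate_dataset

cfg = SimConfig(n=10_000, m=(250, 250), h2=(0.3, 0.3), seed=1)
Y, truth, blocks = simulate_dataset(cfg)

model = TissueMixture(Y, blocks)
res = model.fit(seed=1)
print(res.summary())
print("AUC vs truth:", round(auc(truth.C, res.gamma.gamma[:, 0]), 3))
print(res.classify(0.65).counts)
```

prints

```
Tissue-specific mixture of regressions
  method: map-em    converged: True (24 iterations, delta=1e-05)
  averaged log-likelihood: -2.442544

  tissue                 w     alpha    sigma2_x  sigma2_eps  h2_implied       n_k
  tissue_1          0.5052   -0.0700   1.195e-02      6.3194      0.3210    5048.0
  tissue_2          0.4948    0.0652   9.054e-03      6.9713      0.2451    4952.0
AUC vs truth: 0.676
{'tissue_1': 1715, 'tissue_2': 1644, 'unclassified': 6641}
```

Each row is one tissue component: `w` the estimated fraction of the cohort
whose genetics runs through that tissue (truth: 0.5), `alpha` its baseline
trait mean, `sigma2_x`/`sigma2_eps` the effect-size and residual variances,
and `h2_implied` the implied subtype heritability (truth here: 0.30 for
both).  The AUC measures how well the tissue-1 posterior separates the two
true subgroups; at 30% subtype heritability about two thirds of ranked
pairs are ordered correctly, and 3,359 of 10,000 individuals clear the 65%
posterior threshold.

The same pipeline runs from the shell:

```sh
tissuemix simulate --n 10000 --m 250,250 --h2 0.3,0.3 --seed 1 --out cohort/
tissuemix fit --method map-em --pheno cohort/phenotype.tsv \
    --geno tissue_1=cohort/genotypes_tissue_1.tsv \
    --geno tissue_2=cohort/genotypes_tissue_2.tsv \
    --seed 1 --out fit/
tissuemix evaluate --truth cohort/truth.tsv \
    --responsibilities fit/responsibilities.tsv --out eval/
```

`fit` applies the standard SNP QC (MAF >= 1%, Hardy-Weinberg exact test at
p >= 1e-6, missingness capping with mean imputation) before standardizing
and fitting; `het` scans a trait table for phenome heterogeneity between a
classified group and the remaining population.

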