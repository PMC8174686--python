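"""File formats, cohort assembly, and SNP quality-control filters.

File dialects (all plain delimited text):

* genotype matrix — individuals x SNPs, header row of SNP ids, first column
  the individual id; dosages in {0,1,2}, missing as NA (mean-imputed with a
  logged count; SNPs missing in more than ``max_missing`` of individuals are
  dropped instead);
* phenotype — two columns (individual id, value);
* SNP set — one SNP id per line.

An optional PLINK bed/bim/fam reader feeds the same ``CohortBundle``
contract.  QC per SNP: minor-allele frequency >= ``maf_min`` and
Hardy-Weinberg equilibrium exact-test p-value >= ``hwe_p_min``; every drop
is recorded with its reason.  Retained columns are standardized on the full
sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .params import TissueBlock, check_blocks, standardize_genotypes

__all__ = ["CohortBundle", "load_cohort", "hwe_exact_test", "read_plink",
           "write_cohort"]

logger = logging.getLogger("tissuemix")


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic SNP.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one.  Exact
    rather than chi-square so low-MAF SNPs behave.
    """
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # ensure we count the rarer allele
        return hwe_exact_test(n_hom_major, n_het, n_hom_minor)
    # possible heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    # log P(het | allele counts) up to a shared constant (hypergeometric-type)
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(p[p <= obs * (1 + 1e-12)].sum(), 1.0))


@dataclass
class CohortBundle:
    """Aligned phenotype + per-tissue genotype blocks ready for fitting."""

    individual_ids: np.ndarray
    phenotype: np.ndarray
    blocks: list[TissueBlock]
    filter_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tissue", "snp", "reason"]))
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.phenotype.shape[0]

    def dropped(self, reason: str | None = None) -> pd.DataFrame:
        if reason is None:
            return self.filter_log
        return self.filter_log[self.filter_log["reason"] == reason]


def _qc_columns(raw: pd.DataFrame, tissue: str, maf_min: float,
                hwe_p_min: float, max_missing: float,
                log_rows: list[dict]) -> pd.DataFrame:
    """Apply missingness, MAF and HWE filters; mean-impute surviving NAs."""
    keep = {}
    for snp in raw.columns:
        col = raw[snp].to_numpy(dtype=float)
        miss = np.isnan(col)
        if miss.mean() > max_missing:
            log_rows.append({"tissue": tissue, "snp": snp, "reason": "missingness"})
            continue
        obs = col[~miss]
        if not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            log_rows.append({"tissue": tissue, "snp": snp, "reason": "non_dosage"})
            continue
        freq = obs.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            log_rows.append({"tissue": tissue, "snp": snp, "reason": "maf"})
            continue
        counts = [int((obs == g).sum()) for g in (2.0, 1.0, 0.0)]
        if hwe_exact_test(*counts) < hwe_p_min:
            log_rows.append({"tissue": tissue, "snp": snp, "reason": "hwe"})
            continue
        if miss.any():
            col = np.where(miss, obs.mean(), col)
            logger.info("tissue %s SNP %s: imputed %d missing dosages",
                        tissue, snp, int(miss.sum()))
        keep[snp] = col
    return pd.DataFrame(keep, index=raw.index)


def load_cohort(pheno_path, geno_paths: dict[str, str | Path],
                snp_paths: dict[str, str | Path] | None = None,
                maf_min: float = 0.01, hwe_p_min: float = 1e-6,
                max_missing: float = 0.05, sep: str = "\t") -> CohortBundle:
    """Read, reconcile, filter, and standardize a cohort from delimited text.

    Individuals are intersected across the phenotype and every genotype file
    (dropped counts logged); SNP lists, when given, subset and order each
    tissue's columns.  A SNP appearing in two tissues is a hard error — the
    model assumes non-overlapping sets.
    """
    pheno = pd.read_csv(pheno_path, sep=sep, header=None,
                        names=["individual", "value"], dtype={0: str})
    pheno = pheno.set_index("individual")["value"].astype(float)

    genos: dict[str, pd.DataFrame] = {}
    for tissue, path in geno_paths.items():
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "nan"])
        df.index = df.index.astype(str)
        if snp_paths and tissue in snp_paths:
            wanted = [s.strip() for s in
                      Path(snp_paths[tissue]).read_text().split() if s.strip()]
            missing = sorted(set(wanted) - set(df.columns))
            if missing:
                raise ValueError(
                    f"tissue {tissue!r}: SNPs listed but absent from the "
                    f"genotype file: {missing[:5]}")
            df = df[wanted]
        genos[tissue] = df

    seen: dict[str, str] = {}
    for tissue, df in genos.items():
        for snp in df.columns:
            if snp in seen:
                raise ValueError(
                    f"SNP {snp!r} appears in tissues {seen[snp]!r} and "
                    f"{tissue!r}; tissue-specific sets must be non-overlapping")
            seen[snp] = tissue

    ids = pheno.index
    for df in genos.values():
        ids = ids.intersection(df.index)
    n_dropped = len(pheno) - len(ids)
    if len(ids) == 0:
        raise ValueError("no individuals shared across phenotype and genotypes")
    if n_dropped:
        logger.info("dropped %d individuals absent from some input", n_dropped)
    ids = ids.sort_values()

    log_rows: list[dict] = []
    blocks = []
    for tissue, df in genos.items():
        filtered = _qc_columns(df.loc[ids], tissue, maf_min, hwe_p_min,
                               max_missing, log_rows)
        if filtered.shape[1] == 0:
            raise ValueError(f"tissue {tissue!r}: all SNPs filtered out")
        blocks.append(TissueBlock(
            tissue_id=tissue, snp_ids=list(filtered.columns),
            genotypes=standardize_genotypes(filtered.to_numpy())))
    check_blocks(blocks)
    return CohortBundle(
        individual_ids=ids.to_numpy(), phenotype=pheno.loc[ids].to_numpy(),
        blocks=blocks, filter_log=pd.DataFrame(
            log_rows, columns=["tissue", "snp", "reason"]),
        provenance={"pheno_path": str(pheno_path),
                    "geno_paths": {k: str(v) for k, v in geno_paths.items()},
                    "n_dropped_individuals": int(n_dropped),
                    "maf_min": maf_min, "hwe_p_min": hwe_p_min})


def write_cohort(outdir: str | Path, Y: np.ndarray, blocks: list[TissueBlock],
                 individual_ids=None, sep: str = "\t",
                 extra: dict[str, pd.DataFrame] | None = None) -> dict[str, Path]:
    """Write a cohort in the delimited dialects ``load_cohort`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = (np.asarray(individual_ids) if individual_ids is not None
           else np.array([f"ind{i}" for i in range(len(Y))]))
    paths: dict[str, Path] = {}
    p = outdir / "phenotype.tsv"
    pd.DataFrame({"individual": ids, "value": Y}).to_csv(
        p, sep=sep, index=False, header=False)
    paths["phenotype"] = p
    for b in blocks:
        gp = outdir / f"genotypes_{b.tissue_id}.tsv"
        pd.DataFrame(b.genotypes, index=pd.Index(ids, name="individual"),
                     columns=b.snp_ids).to_csv(gp, sep=sep)
        sp = outdir / f"snps_{b.tissue_id}.txt"
        sp.write_text("\n".join(b.snp_ids) + "\n")
        paths[f"genotypes_{b.tissue_id}"] = gp
        paths[f"snps_{b.tissue_id}"] = sp
    for name, df in (extra or {}).items():
        ep = outdir / f"{name}.tsv"
        df.to_csv(ep, sep=sep, index=False)
        paths[name] = ep
    return paths


def read_plink(prefix: str | Path):
    """Minimal PLINK 1 bed/bim/fam reader (SNP-major, dosage of allele 1).

    Returns (individual ids, SNP ids, float dosage matrix with NaN for
    missing).  Only the standard magic 0x6c 0x1b 0x01 layout is supported.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    iids = fam[1].astype(str).to_numpy()
    snps = bim[1].astype(str).to_numpy()
    n, m = len(iids), len(snps)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or tuple(raw[:3]) != (0x6C, 0x1B, 0x01):
        raise ValueError("not a SNP-major PLINK .bed file")
    stride = (n + 3) // 4
    body = raw[3:].reshape(m, stride)
    # unpack 2-bit genotype codes: 00 hom minor, 01 missing, 10 het, 11 hom major
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, stride * 4)[:, :n]
    lookup = np.array([2.0, np.nan, 1.0, 0.0])
    return iids, snps, lookup[codes].T.copy()
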