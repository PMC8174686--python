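"""Phenome-characterization statistics for tissue-classified groups.

Once individuals are assigned a tissue-specific subtype, these routines ask
whether the group is phenotypically distinct from the remaining population:
an effect-size measure (relative change, in percent of a population standard
deviation), covariate-adjusted and covariate-matched variants of it, and a
scan across many traits using rank-sum / contingency chi-square tests with
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitTable",
    "relative_change",
    "adjusted_relative_change",
    "matched_relative_change",
    "heterogeneity_scan",
]


@dataclass
class TraitTable:
    """Named traits for the fitted cohort.

    ``data`` is indexed by individual ID; ``kinds`` maps each trait name to
    ``"quantitative"`` or ``"categorical"``.  Missing values are NaN and are
    dropped per trait at analysis time.
    """

    data: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ValueError(f"kinds reference unknown traits: {sorted(unknown)}")
        for name, kind in self.kinds.items():
            if kind not in ("quantitative", "categorical"):
                raise ValueError(f"trait {name!r}: unknown kind {kind!r}")
            if kind == "categorical":
                levels = self.data[name].dropna().unique()
                if levels.size < 2:
                    raise ValueError(f"categorical trait {name!r} has <2 levels")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c in self.kinds]


def _check_group(mask: np.ndarray, n: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("group mask length does not match trait vector")
    if not mask.any() or mask.all():
        raise ValueError("group must be a nonempty strict subset")
    return mask


def relative_change(values: np.ndarray, group: np.ndarray,
                    kind: str = "quantitative") -> float:
    """Group-vs-rest effect size in percent of a population sd.

    Quantitative: (group mean - remaining-population mean) / population sd
    x 100.  Binary (disease risk): (group prevalence - population prevalence)
    / population sd of the 0/1 indicator x 100.  The population sd is taken
    over all n individuals, group included.
    """
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    values, group = values[ok], _check_group(group, ok.size)[ok]
    if not group.any() or group.all():
        raise ValueError("group empty (or full) after missingness removal")
    sd = values.std()
    if sd == 0:
        raise ValueError("constant trait: population sd is zero")
    if kind == "quantitative":
        return float((values[group].mean() - values[~group].mean()) / sd * 100.0)
    if kind == "binary":
        levels = np.unique(values)
        if not np.all(np.isin(levels, (0.0, 1.0))):
            raise ValueError("binary trait must be coded 0/1")
        return float((values[group].mean() - values.mean()) / sd * 100.0)
    raise ValueError(f"unknown kind {kind!r}")


def adjusted_relative_change(values: np.ndarray, group: np.ndarray,
                             primary: np.ndarray) -> float:
    """Relative change of the trait after regressing out the primary phenotype.

    A simple linear regression of the trait on the primary phenotype is fit
    over the whole population; relative change is then computed on the
    residuals.  Removes group-vs-rest differences that are merely carried by
    the primary phenotype (e.g. a trait that tracks BMI looking
    adipose-specific only because the adipose group has higher BMI).
    """
    values = np.asarray(values, dtype=float)
    primary = np.asarray(primary, dtype=float)
    if primary.shape != values.shape:
        raise ValueError("primary phenotype must align with the trait vector")
    ok = ~(np.isnan(values) | np.isnan(primary))
    v, p, g = values[ok], primary[ok], _check_group(group, values.size)[ok]
    if p.std() == 0:
        raise ValueError("zero-variance primary phenotype")
    slope, intercept = np.polyfit(p, v, 1)
    resid = v - (intercept + slope * p)
    return relative_change(resid, g, kind="quantitative")


def matched_relative_change(values: np.ndarray, group: np.ndarray,
                            primary: np.ndarray, n_bins: int = 30,
                            n_rep: int = 500, seed: int | None = None,
                            equal_frequency: bool = False
                            ) -> tuple[float, float]:
    """Mean and sd of |relative change| against primary-matched random cohorts.

    The primary phenotype's range *within the group* is split into ``n_bins``
    consecutive non-overlapping bins (equal width by default, equal occupancy
    with ``equal_frequency``).  Per replicate, a random cohort of the group's
    size is drawn from the population with the group's per-bin quotas, so it
    matches the group's primary-phenotype profile; the trait difference
    against that cohort isolates what group genetics contributes beyond the
    primary phenotype.  A bin holding fewer population members than group
    members has its quota capped at availability.
    """
    values = np.asarray(values, dtype=float)
    primary = np.asarray(primary, dtype=float)
    group = _check_group(group, values.size)
    ok = ~(np.isnan(values) | np.isnan(primary))
    v, p, g = values[ok], primary[ok], group[ok]
    if not g.any():
        raise ValueError("group empty after missingness removal")
    sd = v.std()
    if sd == 0:
        raise ValueError("constant trait: population sd is zero")
    pg = p[g]
    if equal_frequency:
        edges = np.unique(np.quantile(pg, np.linspace(0, 1, n_bins + 1)))
    else:
        edges = np.linspace(pg.min(), pg.max(), n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, p, side="right") - 1, 0,
                     len(edges) - 2)
    group_counts = np.bincount(bin_of[g], minlength=len(edges) - 1)
    rng = np.random.default_rng(seed)
    group_mean = v[g].mean()
    changes = np.empty(n_rep)
    pool_by_bin = [np.flatnonzero(bin_of == b) for b in range(len(edges) - 1)]
    for r in range(n_rep):
        picks = []
        for b, want in enumerate(group_counts):
            if want == 0:
                continue
            pool = pool_by_bin[b]
            take = min(int(want), pool.size)  # quota capped at availability
            picks.append(rng.choice(pool, size=take, replace=False))
        matched = np.concatenate(picks)
        changes[r] = abs(group_mean - v[matched].mean()) / sd * 100.0
    return float(changes.mean()), float(changes.std(ddof=1))


def heterogeneity_scan(traits: TraitTable, group: np.ndarray,
                       other_group: np.ndarray | None = None,
                       primary: str | None = None) -> pd.DataFrame:
    """Test every trait for differing between the group and its complement.

    Quantitative traits use the Wilcoxon rank-sum test, categorical traits a
    contingency-table chi-square; p-values are Bonferroni-corrected across
    traits.  ``other_group`` replaces the complement for a group-vs-group
    comparison.  If ``primary`` names a quantitative trait, each quantitative
    trait is also annotated with its relative change and its
    primary-adjusted relative change.
    """
    n = len(traits.data)
    group = _check_group(group, n)
    if other_group is not None:
        other = np.asarray(other_group, dtype=bool)
        if (group & other).any():
            raise ValueError("the two groups overlap")
    else:
        other = ~group
    rows = []
    primary_vals = (traits.data[primary].to_numpy(dtype=float)
                    if primary is not None else None)
    for name in traits.traits:
        kind = traits.kinds[name]
        col = traits.data[name]
        ok = col.notna().to_numpy()
        g_ok, o_ok = group & ok, other & ok
        if not g_ok.any() or not o_ok.any():
            rows.append({"trait": name, "kind": kind, "statistic": np.nan,
                         "p": np.nan, "note": "empty group after missingness"})
            continue
        note = ""
        if kind == "quantitative":
            x = col.to_numpy(dtype=float)
            stat, p = stats.ranksums(x[g_ok], x[o_ok])
            rc = relative_change(np.where(ok, x, np.nan), group)
            arc = (adjusted_relative_change(np.where(ok, x, np.nan), group,
                                            primary_vals)
                   if primary_vals is not None and name != primary else np.nan)
        else:
            sel = g_ok | o_ok
            tab = pd.crosstab(col[sel].astype(str),
                              np.where(group[sel], "group", "rest"))
            chi = stats.chi2_contingency(tab.to_numpy())
            stat, p = float(chi.statistic), float(chi.pvalue)
            if (chi.expected_freq < 5).any():
                note = "expected counts < 5"
            rc = arc = np.nan
        rows.append({"trait": name, "kind": kind, "statistic": float(stat),
                     "p": float(p), "relative_change": rc,
                     "adjusted_relative_change": arc, "note": note})
    out = pd.DataFrame(rows)
    ntests = out["p"].notna().sum()
    out["p_bonferroni"] = np.minimum(out["p"] * ntests, 1.0)
    return out
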