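"""Results containers returned by the fitting engines."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import classify
from .params import ClassificationReport, MixtureParams, ResponsibilityMatrix

__all__ = ["MixtureResults"]


@dataclass
class MixtureResults:
    """Fitted mixture: parameter estimates, responsibilities, and diagnostics.

    Attributes
    ----------
    params : MixtureParams
        Point estimates Theta-hat (MAP or maximum likelihood).
    gamma : ResponsibilityMatrix
        Posterior tissue-membership probabilities at the converged parameters;
        the method's main output.
    loglik_trace : ndarray
        Averaged observed-data log-likelihood per iteration, starting at the
        initialization value.
    converged : bool
        Whether the averaged log-likelihood increment fell to ``delta`` or
        below before ``max_iter`` sweeps.
    """

    params: MixtureParams
    gamma: ResponsibilityMatrix
    loglik_trace: np.ndarray
    iterations: int
    converged: bool
    method: str
    seed: int | None
    delta: float
    warnings: list[str] = field(default_factory=list)

    @property
    def tissue_ids(self) -> list[str]:
        return self.gamma.tissue_ids or [
            f"tissue_{k + 1}" for k in range(self.gamma.K)
        ]

    @property
    def loglik(self) -> float:
        """Final averaged observed-data log-likelihood."""
        return float(self.loglik_trace[-1])

    def classify(self, threshold: float = 0.65) -> ClassificationReport:
        """Hard tissue assignments at a posterior-probability threshold."""
        return classify(self.gamma, threshold=threshold)

    def gamma_frame(self, individual_ids=None) -> pd.DataFrame:
        idx = individual_ids if individual_ids is not None else np.arange(self.gamma.n)
        return pd.DataFrame(self.gamma.gamma, index=pd.Index(idx, name="individual"),
                            columns=self.tissue_ids)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of regression results."""
        lines = [
            "Tissue-specific mixture of regressions",
            f"  method: {self.method}    converged: {self.converged} "
            f"({self.iterations} iterations, delta={self.delta:g})",
            f"  averaged log-likelihood: {self.loglik:.6f}",
            "",
            f"  {'tissue':<16}{'w':>8}{'alpha':>10}{'sigma2_x':>12}"
            f"{'sigma2_eps':>12}{'h2_implied':>12}{'n_k':>10}",
        ]
        n_k = self.gamma.n_k
        for k, (tid, t) in enumerate(zip(self.tissue_ids, self.params.tissues)):
            h2 = t.m * t.sigma2_x / (t.m * t.sigma2_x + t.sigma2_eps)
            lines.append(
                f"  {tid:<16}{t.w:>8.4f}{t.alpha:>10.4f}{t.sigma2_x:>12.3e}"
                f"{t.sigma2_eps:>12.4f}{h2:>12.4f}{n_k[k]:>10.1f}"
            )
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Convergence trace of the averaged log-likelihood."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.loglik_trace)), self.loglik_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("averaged log-likelihood")
        ax.set_title(f"{self.method} convergence")
        return ax

    def save(self, outdir: str | Path, individual_ids=None,
             snp_ids: list[list[str]] | None = None,
             threshold: float = 0.65) -> None:
        """Write parameters (JSON), responsibilities + labels (TSV), trace (CSV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = self.params.to_dict(snp_ids=snp_ids)
        meta.update(
            method=self.method, converged=self.converged,
            iterations=self.iterations, delta=self.delta, seed=self.seed,
            loglik=self.loglik, warnings=self.warnings,
        )
        (outdir / "params.json").write_text(json.dumps(meta, indent=2))
        gf = self.gamma_frame(individual_ids)
        gf["label"] = self.classify(threshold).labels
        gf.to_csv(outdir / "responsibilities.tsv", sep="\t")
        pd.DataFrame({"iteration": np.arange(len(self.loglik_trace)),
                      "avg_loglik": self.loglik_trace}).to_csv(
            outdir / "loglik_trace.csv", index=False)
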