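"""Differential expression between killing and non-killing doublets.

A deliberately simple engine behind the published decision thresholds: per
gene, the log2 fold change of group means on the log2(1 + x) scale and a
two-sided Welch t-test, with Benjamini-Hochberg adjustment across tested
genes. Significance requires adjusted p < alpha AND |log2FC| >= the fold-
change cutoff. The provenance record labels the engine so downstream users
know gene lists come from a moderated-model stand-in, not a precision-
weighted fit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GroupDifferentialExpression", "differential_expression",
           "signature_export", "bh_adjust"]

ENGINE = "welch-log2cpm-bh"   # provenance label for the stand-in test


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


class GroupDifferentialExpression(BaseEstimator):
    """Two-group differential expression on the log2(1 + x) scale.

    ``fit(X, y)`` takes X (cells x genes, non-negative) and y (per-cell
    labels); ``group`` vs ``reference`` selects the contrast (log2FC > 0
    means higher in ``group``). Genes with zero variance in both groups are
    excluded from testing and recorded.

    Attributes
    ----------
    results_ : DataFrame with gene, log2FC, p, p_adj, direction, significant
    excluded_genes_ : list of untestable (flat) genes
    """

    def __init__(self, group: str = "CID_NK_only", reference: str = "CID",
                 alpha: float = 0.05, lfc_threshold: float = 1.0,
                 pseudocount: float = 1.0):
        self.group = group
        self.reference = reference
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y) -> "GroupDifferentialExpression":
        X = pd.DataFrame(X)
        labels = pd.Series(y, index=X.index)
        a_cells = labels.index[labels == self.group]
        b_cells = labels.index[labels == self.reference]
        if len(a_cells) < 3 or len(b_cells) < 3:
            raise ValueError(
                f"both groups need >= 3 cells (got {len(a_cells)} "
                f"{self.group!r}, {len(b_cells)} {self.reference!r})")

        la = np.log2(self.pseudocount + X.loc[a_cells].to_numpy(dtype=float))
        lb = np.log2(self.pseudocount + X.loc[b_cells].to_numpy(dtype=float))
        lfc = la.mean(axis=0) - lb.mean(axis=0)

        flat = (la.var(axis=0) == 0) & (lb.var(axis=0) == 0)
        self.excluded_genes_ = [g for g, f in zip(X.columns, flat) if f]
        if self.excluded_genes_:
            logger.info("%d flat genes excluded from testing",
                        len(self.excluded_genes_))

        genes = [g for g, f in zip(X.columns, flat) if not f]
        keep = ~flat
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = scipy.stats.ttest_ind(la[:, keep], lb[:, keep],
                                         axis=0, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        p_adj = bh_adjust(p)

        res = pd.DataFrame({
            "gene": genes,
            "log2FC": lfc[keep],
            "t": t,
            "p": p,
            "p_adj": p_adj,
        })
        res["direction"] = np.where(res["log2FC"] >= 0, "up", "down")
        res["significant"] = ((res["p_adj"] < self.alpha)
                              & (res["log2FC"].abs() >= self.lfc_threshold))
        self.results_ = res
        return self


def differential_expression(expr: pd.DataFrame, labels: pd.Series,
                            group: str = "CID_NK_only", reference: str = "CID",
                            alpha: float = 0.05, lfc: float = 1.0) -> pd.DataFrame:
    """DE table from a gene x cell matrix (thin wrapper over the estimator)."""
    est = GroupDifferentialExpression(
        group=group, reference=reference, alpha=alpha, lfc_threshold=lfc,
    ).fit(expr.T, labels.reindex(expr.columns))
    return est.results_


def signature_export(de_table: pd.DataFrame, outdir) -> dict[str, list[str]]:
    """Write up/down significant gene lists for external survival tools.

    Returns the exported lists; empty significant sets produce empty files
    with a warning. No survival analysis is performed here.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sig = de_table[de_table["significant"]]
    up = sorted(sig.loc[sig["direction"] == "up", "gene"])
    down = sorted(sig.loc[sig["direction"] == "down", "gene"])
    if not up and not down:
        logger.warning("no significant genes; exporting empty signature files")
    (outdir / "signature_up.txt").write_text("\n".join(up) + ("\n" if up else ""))
    (outdir / "signature_down.txt").write_text("\n".join(down) + ("\n" if down else ""))
    return {"up": up, "down": down}
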