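"""Ligand-receptor co-expression screen across cell groups.

A doublet library contains transcripts of both the NK and the cancer cell, so
coordinated expression of a ligand-receptor pair across doublets is a
surrogate for active signaling between the two cells. The screen restricts to
highly expressed genes, joins them against a curated pair database, computes
the pair correlation within each cell group (doublets, killing-event
doublets, NK singlets, cancer singlets), and qualifies pairs whose
coordination is doublet-specific: correlated in doublets but not explained by
either singlet cell type alone.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["select_top_expressed", "find_pairs", "group_pair_correlations",
           "qualify_pairs", "LRCoexpressionScreen", "run_lr_screen"]

GROUPS = ("CID", "CID_NK_only", "NK", "cancer")
SINGLET_GROUPS = ("NK", "cancer")


def select_top_expressed(expr: pd.DataFrame, top_frac: float = 0.5) -> list[str]:
    """Top fraction of genes by mean expression across all cells.

    Genes are ranked by mean, ties broken by gene id; the top
    ``ceil(top_frac * n_genes)`` are returned.
    """
    if not 0 < top_frac <= 1:
        raise ConfigurationError(f"top_frac must be in (0, 1], got {top_frac}")
    means = expr.mean(axis=1)
    order = sorted(expr.index, key=lambda g: (-means[g], str(g)))
    k = math.ceil(top_frac * len(order))
    return order[:k]


def _normalize_pairs(db: pd.DataFrame) -> pd.DataFrame:
    """Drop self-pairs and unordered duplicates, keeping first occurrence."""
    db = db.copy()
    db = db[db["gene_A"] != db["gene_B"]]
    key = db.apply(lambda r: tuple(sorted((r["gene_A"], r["gene_B"]))), axis=1)
    return db[~key.duplicated()].reset_index(drop=True)


def find_pairs(selected_genes, lr_db: pd.DataFrame,
               known_genes=None) -> pd.DataFrame:
    """Candidate pairs: database entries whose genes are both selected.

    Pairs naming a gene absent from the expression matrix (``known_genes``)
    are dropped with a logged warning before the membership test.
    """
    db = _normalize_pairs(lr_db)
    if known_genes is not None:
        known = set(known_genes)
        bad = ~(db["gene_A"].isin(known) & db["gene_B"].isin(known))
        for _, row in db[bad].iterrows():
            logger.warning("LR pair (%s, %s) names a gene absent from the "
                           "expression matrix; dropped", row.gene_A, row.gene_B)
        db = db[~bad]
    sel = set(selected_genes)
    keep = db["gene_A"].isin(sel) & db["gene_B"].isin(sel)
    return db[keep].reset_index(drop=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    nx, ny = np.sqrt((xs ** 2).sum()), np.sqrt((ys ** 2).sum())
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip((xs @ ys) / (nx * ny), -1.0, 1.0))


def group_pair_correlations(pairs: pd.DataFrame, expr: pd.DataFrame,
                            groups: pd.Series, n_min: int = 5) -> pd.DataFrame:
    """Per-group Pearson correlation of each candidate pair.

    ``groups`` maps cell id -> group label; groups with fewer than ``n_min``
    cells are skipped (NaN for every pair). A zero-variance gene within a
    group yields NaN for that entry with a logged note.
    """
    groups = groups[groups.index.isin(expr.columns)]
    out = pairs.copy()
    for grp in pd.unique(groups):
        cells = groups.index[groups == grp]
        col = f"rho_{grp}"
        if len(cells) < n_min:
            logger.warning("group %s has %d cells (< n_min=%d); skipped",
                           grp, len(cells), n_min)
            out[col] = np.nan
            continue
        sub = expr.loc[:, cells]
        vals = []
        for _, row in pairs.iterrows():
            x = sub.loc[row.gene_A].to_numpy(dtype=float)
            y = sub.loc[row.gene_B].to_numpy(dtype=float)
            r = _pearson(x, y)
            if np.isnan(r):
                logger.warning("pair (%s, %s): zero variance in group %s",
                               row.gene_A, row.gene_B, grp)
            vals.append(r)
        out[col] = vals
    return out


def qualify_pairs(rho_table: pd.DataFrame, cid_threshold: float = 0.4,
                  single_threshold: float = 0.4,
                  cid_group: str = "CID",
                  singlet_groups=SINGLET_GROUPS) -> pd.DataFrame:
    """Flag doublet-specific coordinated pairs.

    A pair qualifies when its correlation in the main doublet group is
    strictly above ``cid_threshold`` and no singlet group shows correlation
    above ``single_threshold`` (which would indicate the co-expression stems
    from one cell type alone). The killing-event doublet group is reported
    but, being small, never decides qualification. All per-group values stay
    in the table so alternative rules can be applied downstream.
    """
    out = rho_table.copy()
    cid_col = f"rho_{cid_group}"
    if cid_col not in out.columns:
        raise ValueError(f"rho table lacks column {cid_col}")
    cid_rho = out[cid_col]
    qualified = cid_rho > cid_threshold
    for grp in singlet_groups:
        col = f"rho_{grp}"
        if col in out.columns:
            qualified &= ~(out[col] > single_threshold)
    out["qualified"] = qualified.fillna(False).astype(bool)
    return out


class LRCoexpressionScreen(BaseEstimator):
    """End-to-end pair screen as a scikit-learn style estimator.

    ``fit(X, y)`` takes X (cells x genes) and y (per-cell group labels),
    selects the top ``top_frac`` genes by mean expression over all cells,
    joins them against ``pair_db``, computes per-group pair correlations and
    qualifies doublet-specific pairs.

    Attributes
    ----------
    selected_genes_ : genes passing the mean-expression cut
    candidate_pairs_ : database pairs with both genes selected
    results_ : candidate pairs with per-group rho and the qualified flag
    qualified_pairs_ : the qualified subset of ``results_``
    """

    def __init__(self, pair_db: pd.DataFrame | None = None, top_frac: float = 0.5,
                 cid_threshold: float = 0.4, single_threshold: float = 0.4,
                 cid_group: str = "CID", n_min: int = 5):
        self.pair_db = pair_db
        self.top_frac = top_frac
        self.cid_threshold = cid_threshold
        self.single_threshold = single_threshold
        self.cid_group = cid_group
        self.n_min = n_min

    def fit(self, X: pd.DataFrame, y) -> "LRCoexpressionScreen":
        if self.pair_db is None:
            raise ConfigurationError("pair_db is required")
        X = pd.DataFrame(X)
        groups = pd.Series(y, index=X.index)
        expr = X.T  # genes x cells
        self.selected_genes_ = select_top_expressed(expr, self.top_frac)
        self.candidate_pairs_ = find_pairs(self.selected_genes_, self.pair_db,
                                           known_genes=expr.index)
        rho = group_pair_correlations(self.candidate_pairs_, expr, groups,
                                      n_min=self.n_min)
        self.results_ = qualify_pairs(rho, self.cid_threshold,
                                      self.single_threshold, self.cid_group)
        self.qualified_pairs_ = self.results_[self.results_["qualified"]]
        return self


def run_lr_screen(expr: pd.DataFrame, groups: pd.Series, pair_db: pd.DataFrame,
                  top_frac: float = 0.5, cid_threshold: float = 0.4,
                  single_threshold: float = 0.4, n_min: int = 5
                  ) -> LRCoexpressionScreen:
    """Screen a gene x cell matrix (thin wrapper over the estimator)."""
    return LRCoexpressionScreen(
        pair_db=pair_db, top_frac=top_frac, cid_threshold=cid_threshold,
        single_threshold=single_threshold, n_min=n_min,
    ).fit(expr.T, groups.reindex(expr.columns))
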