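"""Distance-expression correlation map and memory-gene module discovery.

The core statistic is a gene x timepoint matrix of Pearson coefficients
rho[g, t]: the correlation, across tracked doublets, between the terminal
expression of gene g and the cell-cell distance measured at hour t. Genes
whose terminal state still reflects an earlier distance ("transcriptional
memory") show |rho| peaking at that earlier hour; genes are retained when
|rho| >= 0.25 at one or more hours and partitioned into modules by
hierarchical clustering of their rho rows.

Estimator classes follow scikit-learn conventions (``fit`` + trailing
underscore attributes, ``get_params``/``set_params``); they take cells as
samples (rows). The module-level wrappers accept the field's gene x cell
orientation and transpose internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator, TransformerMixin

from .config import ConfigurationError, FRAME_HOURS

__all__ = [
    "timepoint_policy",
    "VariableGeneSelector",
    "select_variable_genes",
    "DistanceCorrelationMap",
    "CorrelationMap",
    "correlate_distance_expression",
    "select_memory_genes",
    "ModuleClusterer",
    "cluster_modules",
]


def _frame_hour(label: str) -> int:
    try:
        return FRAME_HOURS[label] if label in FRAME_HOURS else int(str(label).lstrip("T").rstrip("p'"))
    except ValueError:
        raise ValueError(f"cannot parse frame label {label!r}") from None


def timepoint_policy(frames, policy: str = "pre-exchange") -> list[str]:
    """Select the analysis timepoints from the available imaging frames.

    The imaging schedule produces 16 frames for 14 hourly labels (T0..T13)
    because the medium-exchange hours 5 and 10 are imaged twice (pre-exchange
    T5/T10 and post-exchange T5p/T10p). Policies:

    - ``"pre-exchange"`` (default): hourly frames T1..Tmax, using the
      pre-exchange image at exchange hours — 13 timepoints for the standard
      schedule.
    - ``"post-exchange"``: as above but T5p/T10p replace T5/T10.
    - ``"include-T0"``: pre-exchange frames plus T0.
    """
    frames = list(frames)
    max_hour = max(_frame_hour(f) for f in frames)
    if policy not in ("pre-exchange", "post-exchange", "include-T0"):
        raise ConfigurationError(f"unknown timepoint policy {policy!r}")
    start = 0 if policy == "include-T0" else 1
    wanted = []
    for h in range(start, max_hour + 1):  # hourly schedule: every hour required
        label = f"T{h}"
        if policy == "post-exchange" and f"T{h}p" in frames:
            label = f"T{h}p"
        wanted.append(label)
    missing = [w for w in wanted if w not in frames]
    if missing:
        raise ValueError(
            f"requested frames {missing} absent; available frames: {frames}")
    return wanted


# ---------------------------------------------------------------------------
# variable-gene selection


class VariableGeneSelector(TransformerMixin, BaseEstimator):
    """Select the ``n_top`` most variable genes on the log1p scale.

    The dispersion statistic is the sample variance of log(1 + x) per gene;
    ties are broken by gene id so selection is deterministic.

    Parameters
    ----------
    n_top : int
        Number of genes to keep. If it exceeds the number available, all
        genes are kept with a warning.
    """

    def __init__(self, n_top: int = 2000):
        self.n_top = n_top

    def fit(self, X: pd.DataFrame, y=None) -> "VariableGeneSelector":
        """X: cells x genes DataFrame of non-negative expression."""
        if self.n_top <= 0:
            raise ConfigurationError(f"n_top must be > 0, got {self.n_top}")
        X = pd.DataFrame(X)
        disp = np.log1p(X.to_numpy(dtype=float)).var(axis=0, ddof=1)
        self.dispersion_ = pd.Series(disp, index=X.columns, name="log1p_variance")
        order = sorted(range(len(disp)), key=lambda i: (-disp[i], str(X.columns[i])))
        k = self.n_top
        if k > len(order):
            warnings.warn(
                f"n_top={k} exceeds {len(order)} available genes; keeping all")
            k = len(order)
        chosen = sorted(order[:k], key=lambda i: i)   # preserve input order
        self.selected_genes_ = [X.columns[i] for i in chosen]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_genes_]


def select_variable_genes(expr: pd.DataFrame, k: int = 2000) -> list[str]:
    """Top-``k`` variable genes of a gene x cell matrix (thin wrapper)."""
    return VariableGeneSelector(n_top=k).fit(expr.T).selected_genes_


# ---------------------------------------------------------------------------
# correlation map


@dataclass
class CorrelationMap:
    """Gene x timepoint Pearson map with the per-entry sample sizes."""

    rho: pd.DataFrame
    n_used: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.rho.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.rho.columns)


class DistanceCorrelationMap(BaseEstimator):
    """Pearson correlation of terminal expression vs per-hour distance.

    ``fit(X, D)`` takes X (doublets x genes) and D (doublets x timepoints,
    NaN where a killing event truncated the trajectory) with matching row
    order, and computes, for every gene g and timepoint t, the correlation
    over pairwise-complete doublets. Entries with fewer than ``n_min``
    complete pairs, or with zero variance on either side, are NaN.

    Attributes
    ----------
    rho_ : DataFrame, genes x timepoints
    n_used_ : DataFrame, complete-pair count per entry
    """

    def __init__(self, n_min: int = 5):
        self.n_min = n_min

    def fit(self, X: pd.DataFrame, D: pd.DataFrame) -> "DistanceCorrelationMap":
        X = pd.DataFrame(X)
        D = pd.DataFrame(D)
        if X.shape[0] != D.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} doublets but D has {D.shape[0]}")
        xv = X.to_numpy(dtype=float)
        rho = np.full((X.shape[1], D.shape[1]), np.nan)
        n_used = np.zeros_like(rho, dtype=int)
        max_n = 0
        for j, t in enumerate(D.columns):
            d = D[t].to_numpy(dtype=float)
            mask = ~np.isnan(d)
            n = int(mask.sum())
            n_used[:, j] = n
            max_n = max(max_n, n)
            if n < max(self.n_min, 2):
                continue
            ds = d[mask] - d[mask].mean()
            dnorm = np.sqrt((ds ** 2).sum())
            xs = xv[mask] - xv[mask].mean(axis=0)
            xnorm = np.sqrt((xs ** 2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xs.T @ ds) / (xnorm * dnorm)
            r[(xnorm == 0) | (dnorm == 0)] = np.nan
            rho[:, j] = np.clip(r, -1.0, 1.0)
        if max_n < 3:
            raise ValueError(
                "fewer than 3 complete expression/distance pairs at every "
                "timepoint; cannot compute the correlation map")
        self.rho_ = pd.DataFrame(rho, index=X.columns, columns=D.columns)
        self.n_used_ = pd.DataFrame(n_used, index=X.columns, columns=D.columns)
        return self


def correlate_distance_expression(
    expr_cid: pd.DataFrame,
    distances: pd.DataFrame,
    timepoints: list[str] | None = None,
    n_min: int = 5,
) -> CorrelationMap:
    """Correlation map from a gene x doublet matrix and a doublet x frame
    distance table (rows matched by position after a shared sort is assumed;
    use :func:`cidmem.preprocess.align_inputs` to build the pair)."""
    if timepoints is None:
        timepoints = timepoint_policy(distances.columns)
    est = DistanceCorrelationMap(n_min=n_min).fit(expr_cid.T, distances[timepoints])
    return CorrelationMap(rho=est.rho_, n_used=est.n_used_)


def select_memory_genes(corrmap: CorrelationMap | pd.DataFrame,
                        threshold: float = 0.25) -> list[str]:
    """Genes with |rho| >= threshold at one or more timepoints (inclusive)."""
    if not 0 < threshold <= 1:
        raise ConfigurationError(
            f"threshold must be in (0, 1], got {threshold}")
    rho = corrmap.rho if isinstance(corrmap, CorrelationMap) else corrmap
    peak = rho.abs().max(axis=1, skipna=True)
    keep = peak >= threshold
    return [g for g, k in zip(rho.index, keep) if k and not np.isnan(peak[g])]


# ---------------------------------------------------------------------------
# module clustering


class ModuleClusterer(BaseEstimator):
    """Hierarchical clustering of correlation-map rows into gene modules.

    Agglomerative clustering (default: average linkage on the Euclidean
    distance between rho rows) cut at exactly ``n_clusters``. Missing rho
    entries are imputed as 0 for clustering only (recorded in
    ``imputed_entries_``). Module labels are renamed M1..Mk by the hour at
    which each cluster's mean |rho| peaks, M1 earliest, so the naming is
    stable across runs.

    Attributes
    ----------
    labels_ : ndarray of module indices (1-based, after peak-hour renaming)
    modules_ : Series mapping gene -> "M1".."Mk"
    linkage_ : scipy linkage matrix (serialized dendrogram)
    peak_hours_ : dict module label -> peak timepoint label
    """

    def __init__(self, n_clusters: int = 4, linkage: str = "average",
                 metric: str = "euclidean"):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric

    def fit(self, R: pd.DataFrame, y=None) -> "ModuleClusterer":
        R = pd.DataFrame(R)
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if self.n_clusters > R.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds {R.shape[0]} retained genes")
        vals = R.to_numpy(dtype=float)
        nan_mask = np.isnan(vals)
        self.imputed_entries_ = int(nan_mask.sum())
        vals = np.where(nan_mask, 0.0, vals)

        self.linkage_ = sch.linkage(vals, method=self.linkage, metric=self.metric)
        raw = sch.cut_tree(self.linkage_, n_clusters=self.n_clusters).ravel()

        # rename clusters by peak hour of the cluster-mean |rho| profile
        order = []
        for c in range(self.n_clusters):
            rows = vals[raw == c]
            profile = np.abs(rows).mean(axis=0)
            order.append((int(profile.argmax()), c))
        order.sort()
        rename = {c: i + 1 for i, (_, c) in enumerate(order)}

        self.labels_ = np.array([rename[c] for c in raw])
        self.modules_ = pd.Series([f"M{l}" for l in self.labels_],
                                  index=R.index, name="module")
        self.peak_hours_ = {f"M{i + 1}": str(R.columns[p])
                            for i, (p, _) in enumerate(order)}
        return self

    def fit_predict(self, R: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(R).labels_


def cluster_modules(corrmap: CorrelationMap | pd.DataFrame, retained: list[str],
                    k: int = 4, linkage: str = "average",
                    metric: str = "euclidean") -> ModuleClusterer:
    """Cluster the retained genes' rho rows into ``k`` modules (thin wrapper)."""
    rho = corrmap.rho if isinstance(corrmap, CorrelationMap) else corrmap
    return ModuleClusterer(n_clusters=k, linkage=linkage, metric=metric).fit(
        rho.loc[retained])
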