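"""Chamber classification, QC filters and input alignment.

The chamber rules turn the start/end composition of each microfluidic chamber
into one retained cell category (NK singlet, cancer singlet, tracked doublet,
killing-event doublet) or an exclusion reason; the QC filters drop
low-complexity cells and rarely detected genes with the boundary semantics
taken literally from the protocol wording ("less than 2000 expressed genes"
is strict; "expression >5 in at least 10 cells" is strict on the value,
inclusive on the cell count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError

logger = logging.getLogger(__name__)

COMPOSITIONS = ("empty", "NK", "cancer", "CID")

RETAINED_CATEGORIES = ("NK", "cancer", "CID", "CID_NK_only")

EXCLUDED_CATEGORIES = (
    "excluded_empty",
    "excluded_cancer_to_empty",
    "excluded_nk_to_empty",
    "excluded_nk_start_cid",
    "excluded_cid_to_cancer",
)

# (start, end) -> category. Chambers empty from the start are excluded
# regardless of the end state.
_RULES: dict[tuple[str, str], str] = {
    ("cancer", "empty"): "excluded_cancer_to_empty",
    ("NK", "empty"): "excluded_nk_to_empty",
    ("NK", "CID"): "excluded_nk_start_cid",
    ("CID", "cancer"): "excluded_cid_to_cancer",
    ("NK", "NK"): "NK",
    ("cancer", "cancer"): "cancer",
    ("CID", "CID"): "CID",
    ("CID", "NK"): "CID_NK_only",
}


class ManifestParseError(ValueError):
    """A manifest row with an unknown composition label or no classification rule."""


class AlignmentError(ValueError):
    """Expression and distance tables share no doublet."""


def classify_chambers(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Assign each chamber exactly one category and tally the exclusions.

    Returns the manifest with a ``category`` column plus a report dict with
    per-category counts, the excluded/retained totals and the manifest size
    (the counts always sum to the manifest size).
    """
    manifest = manifest.copy()
    categories = []
    for i, row in manifest.iterrows():
        start, end = row["start_composition"], row["end_composition"]
        for label in (start, end):
            if label not in COMPOSITIONS:
                raise ManifestParseError(
                    f"row {i} (chamber {row.get('chamber_id', '?')}): unknown "
                    f"composition {label!r}; expected one of {COMPOSITIONS}")
        if start == "empty":
            categories.append("excluded_empty")
            continue
        try:
            categories.append(_RULES[(start, end)])
        except KeyError:
            raise ManifestParseError(
                f"row {i} (chamber {row.get('chamber_id', '?')}): no "
                f"classification rule for {start!r} -> {end!r}") from None
    manifest["category"] = categories

    counts = {c: int((manifest["category"] == c).sum())
              for c in EXCLUDED_CATEGORIES + RETAINED_CATEGORIES}
    report = {
        "counts": counts,
        "n_excluded": sum(counts[c] for c in EXCLUDED_CATEGORIES),
        "n_retained": sum(counts[c] for c in RETAINED_CATEGORIES),
        "n_total": int(len(manifest)),
    }
    return manifest, report


def filter_cells(expr: pd.DataFrame, min_expressed_genes: int = 2000) -> pd.DataFrame:
    """Drop cells with fewer than ``min_expressed_genes`` non-zero genes.

    "Expressed" means strictly positive; a cell with exactly the threshold
    count is retained. Column order of survivors is preserved.
    """
    if min_expressed_genes < 0:
        raise ConfigurationError(
            f"min_expressed_genes must be >= 0, got {min_expressed_genes}")
    n_expressed = (expr.to_numpy() > 0).sum(axis=0)
    keep = n_expressed >= min_expressed_genes
    return expr.loc[:, keep]


def filter_genes(expr: pd.DataFrame, min_value: float = 5.0,
                 min_cells: int = 10) -> pd.DataFrame:
    """Keep genes with expression strictly above ``min_value`` in at least
    ``min_cells`` cells. Row order of survivors is preserved."""
    if min_cells < 0:
        raise ConfigurationError(f"min_cells must be >= 0, got {min_cells}")
    n_above = (expr.to_numpy() > min_value).sum(axis=1)
    return expr.loc[n_above >= min_cells, :]


def apply_filters(expr: pd.DataFrame, min_expressed_genes: int = 2000,
                  min_value: float = 5.0, min_cells: int = 10) -> pd.DataFrame:
    """Cell filter followed by gene filter — the pipeline's documented order.

    The order matters: dropping low-complexity cells first changes which
    genes clear the detection threshold.
    """
    return filter_genes(filter_cells(expr, min_expressed_genes),
                        min_value, min_cells)


class ZeroVarianceError(ValueError):
    pass


def zscore_channels(intensities: pd.DataFrame,
                    channels: tuple[str, ...] = ("nk_channel", "cancer_channel")
                    ) -> pd.DataFrame:
    """Z-score each staining channel independently (mean 0, sample SD 1)."""
    out = intensities.copy()
    if len(out) < 2:
        raise ValueError("need at least 2 cells per channel to z-score")
    for ch in channels:
        if ch not in out.columns:
            raise ValueError(f"channel column {ch!r} not found")
        vals = out[ch].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ZeroVarianceError(f"channel {ch!r} has zero variance")
        out[ch] = (vals - vals.mean()) / sd
    return out


@dataclass
class AnalysisBundle:
    """Sequenced doublets with expression and distance rows aligned 1:1."""

    expression: pd.DataFrame      # genes x CIDs
    distances: pd.DataFrame       # CIDs x frames, same CID order
    n_cid: int
    dropped_expression: list[str] = field(default_factory=list)
    dropped_distance: list[str] = field(default_factory=list)


def align_inputs(expr: pd.DataFrame, distances: pd.DataFrame,
                 classified_manifest: pd.DataFrame) -> AnalysisBundle:
    """Pair the sequenced tracked-doublet expression columns with their
    distance trajectories.

    Doublets present on only one side are dropped with a warning; the result
    is sorted by chamber id so that input row order is irrelevant.
    """
    if "category" not in classified_manifest.columns:
        raise ValueError("manifest must be classified first (no category column)")
    mask = classified_manifest["category"] == "CID"
    if "sequenced" in classified_manifest.columns:
        mask &= classified_manifest["sequenced"].astype(bool)
    cid_ids = set(classified_manifest.loc[mask, "chamber_id"])

    in_expr = [c for c in expr.columns if c in cid_ids]
    in_dist = set(distances.index)
    common = sorted(set(in_expr) & in_dist)
    if not common:
        raise AlignmentError("no sequenced doublet appears in both the "
                             "expression matrix and the distance table")
    dropped_expr = sorted(set(in_expr) - in_dist)
    dropped_dist = sorted((in_dist & cid_ids) - set(in_expr))
    unknown = sorted(in_dist - cid_ids)
    for cid in dropped_expr:
        logger.warning("doublet %s has expression but no distance record; dropped", cid)
    for cid in dropped_dist:
        logger.warning("doublet %s has distances but no expression column; dropped", cid)
    if unknown:
        logger.warning("%d distance rows are not sequenced doublets in the "
                       "manifest (e.g. %s); ignored", len(unknown), unknown[:3])

    return AnalysisBundle(
        expression=expr.loc[:, common],
        distances=distances.loc[common],
        n_cid=len(common),
        dropped_expression=dropped_expr,
        dropped_distance=dropped_dist,
    )
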