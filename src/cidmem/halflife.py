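"""mRNA half-life association of the memory-gene modules.

Tests whether module genes (those whose terminal expression tracks earlier
cell-cell distances) degrade more slowly than background genes: a longer
half-life lets an early regulatory event remain visible in the terminal
transcriptome. The comparison is a two-sided Welch two-sample t-test on
half-lives in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["HalfLifeJoin", "join_half_lives", "WelchResult", "welch_test",
           "module_halflife_report"]


@dataclass
class HalfLifeJoin:
    matched: pd.DataFrame          # gene, half_life_hours for matched genes
    n_matched: int
    n_unmatched: int
    mean_halflife: float           # mean over matched genes (NaN if none)
    status: str                    # "ok" or "empty"


def join_half_lives(genes, table: pd.DataFrame) -> HalfLifeJoin:
    """Inner join of a gene set against the half-life resource.

    Gene ids are case-normalized before matching. The half-life table is
    expected to carry columns ``gene`` and ``half_life_hours``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    tab = table.copy()
    tab["_key"] = tab["gene"].astype(str).str.upper()
    tab = tab.drop_duplicates("_key")
    keys = {str(g).upper(): g for g in genes}
    hit = tab[tab["_key"].isin(keys)]
    matched = pd.DataFrame({
        "gene": [keys[k] for k in hit["_key"]],
        "half_life_hours": hit["half_life_hours"].to_numpy(dtype=float),
    })
    n_matched = len(matched)
    return HalfLifeJoin(
        matched=matched,
        n_matched=n_matched,
        n_unmatched=len(genes) - n_matched,
        mean_halflife=float(matched["half_life_hours"].mean()) if n_matched else float("nan"),
        status="ok" if n_matched else "empty",
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float

    def to_dict(self) -> dict:
        return asdict(self)


def welch_test(a, b) -> WelchResult:
    """Two-sided Welch two-sample t-test with Welch-Satterthwaite df.

    Both groups need >= 2 values. If both groups have zero variance and equal
    means the test is declared uninformative with t = 0, p = 1; zero variance
    with unequal means is rejected as degenerate input.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 values (got {a.size} and {b.size})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    common = dict(n_a=a.size, n_b=b.size,
                  mean_a=float(a.mean()), mean_b=float(b.mean()),
                  median_a=float(np.median(a)), median_b=float(np.median(b)))
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        if math.isclose(a.mean(), b.mean()):
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0, **common)
        raise ValueError("both groups have zero variance but different means")
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / a.size) ** 2 / (a.size - 1)
                     + (vb / b.size) ** 2 / (b.size - 1))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(max(p, 0.0), 1.0), **common)


def module_halflife_report(module_genes, halflife_table: pd.DataFrame,
                           background: str = "table",
                           gene_universe=None) -> dict:
    """Module-vs-background half-life comparison.

    ``background="table"`` (default): background is every half-life-table
    gene not in the modules. ``background="universe"``: background is
    ``gene_universe`` minus the modules, joined against the table.
    Returns a JSON-serializable report; ``status`` is ``"skipped"`` when
    either group is too small to test.
    """
    module_genes = list(module_genes)
    join = join_half_lives(module_genes, halflife_table)
    mod_keys = {str(g).upper() for g in module_genes}
    if background == "table":
        bg = halflife_table[~halflife_table["gene"].astype(str).str.upper()
                            .isin(mod_keys)]
        bg_values = bg["half_life_hours"].to_numpy(dtype=float)
        n_bg_unmatched = 0
    elif background == "universe":
        if gene_universe is None:
            raise ValueError('background="universe" requires gene_universe')
        bg_genes = [g for g in gene_universe if str(g).upper() not in mod_keys]
        bg_join = join_half_lives(bg_genes, halflife_table)
        bg_values = bg_join.matched["half_life_hours"].to_numpy(dtype=float)
        n_bg_unmatched = bg_join.n_unmatched
    else:
        raise ValueError(f"unknown background mode {background!r}")

    report = {
        "n_module_genes": len(module_genes),
        "n_matched": join.n_matched,
        "n_unmatched": join.n_unmatched,
        "mean_module_halflife": join.mean_halflife,
        "n_background": int(bg_values.size),
        "n_background_unmatched": n_bg_unmatched,
        "background_mode": background,
    }
    if join.n_matched < 2 or bg_values.size < 2:
        report["status"] = "skipped"
        report["reason"] = "fewer than 2 half-life values in a group"
        return report
    res = welch_test(join.matched["half_life_hours"].to_numpy(), bg_values)
    report["status"] = "ok"
    report["welch"] = res.to_dict()
    return report
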