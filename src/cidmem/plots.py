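"""Figure-style outputs: module heatmap, half-life boxplot, LR barplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
import seaborn as sns  # noqa: E402


def module_heatmap(rho: pd.DataFrame, modules: pd.Series, path,
                   exchange_hours=(5, 10)) -> None:
    """Gene x timepoint correlation heatmap, rows grouped by module.

    Viridis colour scale (high correlation yellow, low purple); red arrows
    mark the medium-exchange timepoints.
    """
    order = modules.sort_values(kind="stable").index
    data = rho.loc[order]
    fig, ax = plt.subplots(figsize=(7, max(3, 0.08 * len(order))))
    sns.heatmap(data, cmap="viridis", center=0, ax=ax,
                cbar_kws={"label": "Pearson correlation"})
    # module boundaries
    counts = modules.loc[order].value_counts().sort_index()
    edge = 0
    for m, n in counts.items():
        edge += n
        ax.axhline(edge, color="white", lw=1)
    cols = list(data.columns)
    for h in exchange_hours:
        lab = f"T{h}"
        if lab in cols:
            x = cols.index(lab) + 0.5
            ax.annotate("", xy=(x, 0), xytext=(x, -0.03 * max(len(order), 10)),
                        arrowprops=dict(color="red", arrowstyle="-|>"),
                        annotation_clip=False)
    ax.set_xlabel("timepoint")
    ax.set_ylabel("gene (grouped by module)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def halflife_boxplot(module_hl, background_hl, path, p_value=None) -> None:
    """Module vs background mRNA half-life distributions."""
    fig, ax = plt.subplots(figsize=(4, 4))
    data = [np.asarray(module_hl, dtype=float),
            np.asarray(background_hl, dtype=float)]
    ax.boxplot(data, tick_labels=["module", "background"], showfliers=False)
    ax.set_ylabel("mRNA half-life (h)")
    if p_value is not None:
        ax.set_title(f"Welch two-sample t-test, p = {p_value:.4g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def lr_barplot(rho_row: pd.Series, path, groups=("CID", "CID_NK_only", "NK", "cancer")) -> None:
    """Per-group correlation bars for one ligand-receptor pair."""
    vals, labels = [], []
    for g in groups:
        col = f"rho_{g}"
        if col in rho_row.index:
            vals.append(rho_row[col])
            labels.append(g)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.bar(labels, vals, color=["#8856a7" if l.startswith("CID") else "#bdbdbd"
                                for l in labels])
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("Pearson correlation")
    ax.set_ylim(-1, 1)
    ax.set_title(f"{rho_row['gene_A']} / {rho_row['gene_B']}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
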