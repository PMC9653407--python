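"""End-to-end orchestration: preprocess -> correlate -> modules -> half-life
-> ligand-receptor screen -> killing differential expression.

Every stage writes its tabular outputs into the run directory; the run ends
with a resolved configuration, a provenance record and an output manifest
with content hashes, so a run can be audited and re-executed byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import plots
from .config import ConfigurationError
from .correlation import (cluster_modules, correlate_distance_expression,
                          select_memory_genes, select_variable_genes,
                          timepoint_policy)
from .de import ENGINE, differential_expression, signature_export
from .halflife import module_halflife_report
from .lr import run_lr_screen
from .preprocess import (align_inputs, apply_filters, classify_chambers,
                         filter_cells, filter_genes, zscore_channels)

logger = logging.getLogger(__name__)

_POLICIES = ("pre-exchange", "post-exchange", "include-T0")


class StageError(RuntimeError):
    """A named pipeline stage failed."""


@dataclass
class PipelineConfig:
    """Input paths and every analysis threshold, with validated ranges."""

    manifest: str = ""
    expression: str = ""
    distances: str = ""
    halflife: str = ""            # optional: empty string skips the stage
    lr_pairs: str = ""            # optional
    channels: str = ""            # optional
    coding_genes: str = ""        # optional allow-list file
    halflife_units: str = "hours"
    batch_corrected: bool = False
    min_expressed_genes: int = 2000
    gene_min_value: float = 5.0
    gene_min_cells: int = 10
    hvg_k: int = 2000
    rho_threshold: float = 0.25
    k_modules: int = 4
    timepoint_policy: str = "pre-exchange"
    linkage: str = "average"
    metric: str = "euclidean"
    halflife_background: str = "table"
    top_frac: float = 0.5
    cid_threshold: float = 0.4
    single_threshold: float = 0.4
    alpha: float = 0.05
    lfc: float = 1.0
    n_min: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.rho_threshold <= 1, "rho_threshold must be in (0, 1]"),
            (0 < self.top_frac <= 1, "top_frac must be in (0, 1]"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.lfc >= 0, "lfc must be >= 0"),
            (self.k_modules >= 1, "k_modules must be >= 1"),
            (self.hvg_k >= 1, "hvg_k must be >= 1"),
            (self.min_expressed_genes >= 0, "min_expressed_genes must be >= 0"),
            (self.gene_min_cells >= 0, "gene_min_cells must be >= 0"),
            (self.n_min >= 2, "n_min must be >= 2"),
            (self.timepoint_policy in _POLICIES,
             f"timepoint_policy must be one of {_POLICIES}"),
            (-1 <= self.cid_threshold <= 1, "cid_threshold must be in [-1, 1]"),
            (-1 <= self.single_threshold <= 1, "single_threshold must be in [-1, 1]"),
            (self.halflife_background in ("table", "universe"),
             "halflife_background must be 'table' or 'universe'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResults:
    """In-memory handles to the main per-stage results of a run."""

    outdir: Path
    exclusion_report: dict
    classified_manifest: pd.DataFrame
    filtered_expression: pd.DataFrame
    n_cid: int
    correlation_rho: pd.DataFrame | None = None
    memory_genes: list = field(default_factory=list)
    modules: pd.Series | None = None
    halflife_report: dict | None = None
    lr_results: pd.DataFrame | None = None
    de_results: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.monotonic()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise StageError(f"stage {name!r} failed: {e}") from e
            logger.info("stage %s finished in %.2f s", name, time.monotonic() - t0)
            return out
        return wrapper
    return deco


def _read_expression(path: str) -> pd.DataFrame:
    if str(path).endswith(".mtx"):
        return _io.read_expression_mtx(path)
    return _io.read_expression_tsv(path)


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResults:
    """Execute every stage on the configured inputs, writing into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)

    # fail-fast input validation before any stage runs
    required = {"manifest": config.manifest, "expression": config.expression,
                "distances": config.distances}
    optional = {"halflife": config.halflife, "lr_pairs": config.lr_pairs,
                "channels": config.channels, "coding_genes": config.coding_genes}
    for name, path in required.items():
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} not found: {path!r}")
    for name, path in optional.items():
        if path and not Path(path).exists():
            raise FileNotFoundError(f"configured input {name!r} not found: {path!r}")

    provenance: dict = {"config": config.to_dict(), "engine_de": ENGINE,
                        "batch_corrected": config.batch_corrected}

    manifest = _io.read_manifest(config.manifest)
    expr = _read_expression(config.expression)
    distances = _io.read_distances(config.distances)

    # --- preprocess ------------------------------------------------------
    classified, report = _stage("classify")(classify_chambers)(manifest)
    classified.to_csv(outdir / "exclusion_report.tsv", sep="\t", index=False)

    retained_cells = classified.loc[
        classified["category"].isin(("NK", "cancer", "CID", "CID_NK_only")),
        "chamber_id"]
    expr = expr.loc[:, [c for c in expr.columns if c in set(retained_cells)]]

    if config.coding_genes:
        allow = set(_io.read_gene_list(config.coding_genes))
        before = expr.shape[0]
        expr = expr.loc[[g for g in expr.index if g in allow]]
        provenance["coding_gene_filter"] = {"before": before, "after": expr.shape[0]}

    n0 = expr.shape
    expr = _stage("filter_cells")(filter_cells)(expr, config.min_expressed_genes)
    n1 = expr.shape
    expr = _stage("filter_genes")(filter_genes)(
        expr, config.gene_min_value, config.gene_min_cells)
    provenance["filters"] = {
        "order": ["cells", "genes"],
        "cells_before": n0[1], "cells_after": n1[1],
        "genes_before": n0[0], "genes_after": expr.shape[0],
    }
    _io.write_expression_tsv(expr, outdir / "expression_filtered.tsv")

    if config.channels:
        channels = pd.read_csv(config.channels, sep="\t")
        z = _stage("zscore_channels")(zscore_channels)(channels)
        z.to_csv(outdir / "channels_zscored.tsv", sep="\t", index=False)

    categories = classified.set_index("chamber_id")["category"]
    bundle = _stage("align")(align_inputs)(expr, distances, classified)
    provenance["n_cid_aligned"] = bundle.n_cid

    results = PipelineResults(outdir=outdir, exclusion_report=report,
                              classified_manifest=classified,
                              filtered_expression=expr, n_cid=bundle.n_cid,
                              provenance=provenance)

    # --- correlation map and modules -------------------------------------
    def correlate():
        tps = timepoint_policy(bundle.distances.columns, config.timepoint_policy)
        provenance["timepoints"] = tps
        hvg = select_variable_genes(bundle.expression, config.hvg_k)
        provenance["hvg"] = {"statistic": "log1p_variance", "k": len(hvg)}
        corr = correlate_distance_expression(
            bundle.expression.loc[hvg], bundle.distances, tps, n_min=config.n_min)
        corr.rho.to_csv(outdir / "rho_matrix.tsv", sep="\t")
        memory = select_memory_genes(corr, config.rho_threshold)
        (outdir / "memory_genes.txt").write_text("\n".join(memory) + ("\n" if memory else ""))
        modules = None
        if len(memory) >= config.k_modules:
            clust = cluster_modules(corr, memory, config.k_modules,
                                    config.linkage, config.metric)
            modules = clust.modules_
            provenance["module_imputed_entries"] = clust.imputed_entries_
            provenance["module_peak_hours"] = clust.peak_hours_
            modules.rename_axis("gene").reset_index().to_csv(
                outdir / "modules.tsv", sep="\t", index=False)
            plots.module_heatmap(corr.rho.loc[memory], modules,
                                 outdir / "modules_heatmap.png")
        else:
            provenance["modules_skipped"] = (
                f"only {len(memory)} memory genes for k={config.k_modules}")
        return corr, memory, modules

    corr, memory, modules = _stage("correlate")(correlate)()
    results.correlation_rho = corr.rho
    results.memory_genes = memory
    results.modules = modules

    # --- half-life association -------------------------------------------
    if config.halflife and modules is not None:
        def halflife_stage():
            table = _io.read_halflife(config.halflife, config.halflife_units)
            rep = module_halflife_report(
                list(modules.index), table,
                background=config.halflife_background,
                gene_universe=list(expr.index))
            (outdir / "halflife_report.json").write_text(json.dumps(rep, indent=1))
            if rep["status"] == "ok":
                mod_keys = {str(g).upper() for g in modules.index}
                tab = table.copy()
                is_mod = tab["gene"].astype(str).str.upper().isin(mod_keys)
                plots.halflife_boxplot(
                    tab.loc[is_mod, "half_life_hours"],
                    tab.loc[~is_mod, "half_life_hours"],
                    outdir / "halflife_boxplot.png", p_value=rep["welch"]["p"])
            return rep

        results.halflife_report = _stage("halflife")(halflife_stage)()

    # --- ligand-receptor screen ------------------------------------------
    if config.lr_pairs:
        def lr_stage():
            db = _io.read_lr_pairs(config.lr_pairs)
            screen = run_lr_screen(expr, categories, db,
                                   top_frac=config.top_frac,
                                   cid_threshold=config.cid_threshold,
                                   single_threshold=config.single_threshold,
                                   n_min=config.n_min)
            screen.results_.to_csv(outdir / "lr_results.tsv", sep="\t", index=False)
            for i, (_, row) in enumerate(screen.qualified_pairs_.iterrows()):
                if i >= 12:
                    break
                plots.lr_barplot(row, outdir / f"lr_pair_{row.gene_A}_{row.gene_B}.png")
            return screen.results_

        results.lr_results = _stage("lr")(lr_stage)()

    # --- killing-event differential expression ---------------------------
    def de_stage():
        de = differential_expression(expr, categories,
                                     group="CID_NK_only", reference="CID",
                                     alpha=config.alpha, lfc=config.lfc)
        de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        signature_export(de, outdir)
        return de

    results.de_results = _stage("de")(de_stage)()

    # --- provenance, output manifest, report ------------------------------
    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    _io.write_provenance(outdir / "provenance.json", provenance)
    outputs = sorted(p for p in outdir.iterdir()
                     if p.is_file() and p.name != "output_manifest.json"
                     and p.name != "run.log")
    manifest_rec = {p.name: _io.sha256_file(p) for p in outputs}
    (outdir / "output_manifest.json").write_text(
        json.dumps(manifest_rec, indent=1, sort_keys=True))
    render_report(outdir)
    return results


def _setup_logging(outdir: Path) -> None:
    root = logging.getLogger("cidmem")
    root.setLevel(logging.INFO)
    have = {getattr(h, "_cidmem_tag", None) for h in root.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._cidmem_tag = "stderr"
        root.addHandler(h)
    fh = logging.FileHandler(outdir / "run.log")
    fh._cidmem_tag = "file"
    root.handlers = [h for h in root.handlers
                     if getattr(h, "_cidmem_tag", None) != "file"]
    root.addHandler(fh)


# ---------------------------------------------------------------------------
# report


def render_report(results_dir) -> Path:
    """Assemble ``report.md`` from the saved outputs of a completed run.

    Pure function of the files on disk: regenerating from the same outputs
    yields a byte-identical report. Missing stages are marked skipped.
    """
    d = Path(results_dir)
    lines = ["# Doublet distance-expression analysis report", ""]

    prov = {}
    if (d / "provenance.json").exists():
        prov = json.loads((d / "provenance.json").read_text())
        cfg = prov.get("config", {})
        lines += ["## Thresholds", ""]
        for key in ("min_expressed_genes", "gene_min_value", "gene_min_cells",
                    "hvg_k", "rho_threshold", "k_modules", "timepoint_policy",
                    "top_frac", "cid_threshold", "single_threshold", "alpha",
                    "lfc", "n_min", "seed"):
            lines.append(f"- {key}: {cfg.get(key)}")
        lines.append("")

    if (d / "exclusion_report.tsv").exists():
        cls = pd.read_csv(d / "exclusion_report.tsv", sep="\t")
        counts = cls["category"].value_counts().sort_index()
        lines += ["## Chamber classification", ""]
        lines += [f"- {cat}: {n}" for cat, n in counts.items()]
        excluded = int(counts[[c for c in counts.index
                               if str(c).startswith("excluded")]].sum())
        lines += [f"- total excluded: {excluded}",
                  f"- total retained: {int(counts.sum()) - excluded}", ""]
    else:
        lines += ["## Chamber classification", "", "_stage skipped_", ""]

    lines += ["## Memory modules", ""]
    if (d / "modules.tsv").exists():
        mods = pd.read_csv(d / "modules.tsv", sep="\t")
        lines.append(f"- memory genes retained: {len(mods)}")
        for m, n in mods["module"].value_counts().sort_index().items():
            peak = prov.get("module_peak_hours", {}).get(m, "?")
            lines.append(f"- {m}: {n} genes (peak {peak})")
        lines += ["", "![module heatmap](modules_heatmap.png)", ""]
    elif (d / "memory_genes.txt").exists():
        n = len([g for g in (d / "memory_genes.txt").read_text().split() if g])
        lines += [f"- memory genes retained: {n}",
                  "- module clustering: _stage skipped_", ""]
    else:
        lines += ["_stage skipped_", ""]

    lines += ["## mRNA half-life", ""]
    if (d / "halflife_report.json").exists():
        rep = json.loads((d / "halflife_report.json").read_text())
        lines.append(f"- matched module genes: {rep['n_matched']} "
                     f"(mean half-life {rep['mean_module_halflife']:.3g} h)")
        if rep.get("status") == "ok":
            w = rep["welch"]
            lines += [f"- Welch two-sample t-test: t = {w['t']:.3g}, "
                      f"df = {w['df']:.3g}, p = {w['p']:.4g}",
                      f"- medians (module vs background): {w['median_a']:.3g} h "
                      f"vs {w['median_b']:.3g} h",
                      "", "![half-life boxplot](halflife_boxplot.png)", ""]
        else:
            lines += [f"- test skipped: {rep.get('reason', '')}", ""]
    else:
        lines += ["_stage skipped_", ""]

    lines += ["## Ligand-receptor screen", ""]
    if (d / "lr_results.tsv").exists():
        lr = pd.read_csv(d / "lr_results.tsv", sep="\t")
        q = lr[lr["qualified"]]
        lines.append(f"- candidate pairs: {len(lr)}")
        lines.append(f"- qualified doublet-specific pairs: {len(q)}")
        for _, row in q.iterrows():
            lines.append(f"  - {row.gene_A}/{row.gene_B} "
                         f"(rho_CID = {row.get('rho_CID', float('nan')):.3g})")
        lines.append("")
    else:
        lines += ["_stage skipped_", ""]

    lines += ["## Killing-event differential expression", ""]
    if (d / "de_results.tsv").exists():
        de = pd.read_csv(d / "de_results.tsv", sep="\t")
        sig = de[de["significant"]]
        up = sig[sig["direction"] == "up"]
        lines += [f"- genes tested: {len(de)}",
                  f"- significant: {len(sig)} ({len(up)} up, {len(sig) - len(up)} down)",
                  ""]
        head = sig.sort_values("p_adj").head(10)
        if len(head):
            lines += ["| gene | log2FC | p_adj |", "|---|---|---|"]
            lines += [f"| {r.gene} | {r.log2FC:.3g} | {r.p_adj:.3g} |"
                      for r in head.itertuples()]
            lines.append("")
    else:
        lines += ["_stage skipped_", ""]

    path = d / "report.md"
    path.write_text("\n".join(lines))
    return path
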