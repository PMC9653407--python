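"""Synthetic doublet-tracking experiment generator.

Emulates the five inputs of the analysis — chamber manifest, terminal gene x
cell expression matrix, per-timepoint cell-cell distance table, mRNA half-life
resource, and ligand-receptor pair database — with the statistical structure
the downstream stages assume, plus a ground-truth record for parameter
recovery tests.

The mechanistic core is a memory kernel: the terminal expression of a planted
"module" gene reflects the cell-cell distance history weighted by
``w_g(t) = exp(-(t*_g - t) * ln2 / tau_g)`` for hours ``t <= t*_g``, where
``t*_g`` is the gene's activity peak and ``tau_g`` its mRNA half-life. Longer
half-lives let earlier distances remain visible in the terminal transcriptome,
which is exactly the signal the correlation map is designed to detect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, ConfigurationError, FRAME_HOURS

__all__ = [
    "GroundTruth",
    "SimulatedBundle",
    "make_ground_truth",
    "simulate_manifest",
    "simulate_distances",
    "simulate_expression",
    "simulate_channels",
    "simulate_lr_inputs",
    "simulate_all",
    "write_bundle",
]

# stable sub-stream keys so each operation is reproducible on its own
_STREAM_TRUTH = 0
_STREAM_DISTANCES = 1
_STREAM_EXPRESSION = 2
_STREAM_MANIFEST = 3
_STREAM_LR = 4
_STREAM_CHANNELS = 5


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """Planted structure of one simulated experiment."""

    genes: list[str]
    module_membership: dict[str, str]          # gene -> "M1".."Mk"
    half_life: dict[str, float]                # gene -> hours (all genes)
    peak_hour: dict[str, int]                  # module gene -> hour index
    coupling_sign: dict[str, int]              # module gene -> +1 / -1
    coordinated_pairs: list[tuple[str, str]]
    null_pairs: list[tuple[str, str]]
    kill_hours: dict[str, int]                 # killing chamber -> hour
    de_genes: dict[str, float]                 # gene -> planted log2FC
    nk_markers: list[str]
    cancer_markers: list[str]

    def module_genes(self) -> list[str]:
        return list(self.module_membership)

    def to_json(self) -> str:
        d = {
            "genes": self.genes,
            "module_membership": self.module_membership,
            "half_life": self.half_life,
            "peak_hour": self.peak_hour,
            "coupling_sign": self.coupling_sign,
            "coordinated_pairs": [list(p) for p in self.coordinated_pairs],
            "null_pairs": [list(p) for p in self.null_pairs],
            "kill_hours": self.kill_hours,
            "de_genes": self.de_genes,
            "nk_markers": self.nk_markers,
            "cancer_markers": self.cancer_markers,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["coordinated_pairs"] = [tuple(p) for p in d["coordinated_pairs"]]
        d["null_pairs"] = [tuple(p) for p in d["null_pairs"]]
        d["peak_hour"] = {g: int(v) for g, v in d["peak_hour"].items()}
        d["kill_hours"] = {c: int(v) for c, v in d["kill_hours"].items()}
        d["coupling_sign"] = {g: int(v) for g, v in d["coupling_sign"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# chamber layout


def _chamber_layout(config: SimulationConfig) -> pd.DataFrame:
    """Fixed chamber composition table (ids, start/end state) for a run.

    The block order is deterministic so that every generator stage agrees on
    which chamber is which without passing tables around.
    """
    blocks = [
        ("empty", "empty", config.n_empty),
        ("cancer", "empty", config.n_cancer_to_empty),
        ("NK", "empty", config.n_nk_to_empty),
        ("NK", "CID", config.n_nk_start_cid),
        ("CID", "cancer", config.n_cid_to_cancer),
        ("NK", "NK", config.n_single_nk),
        ("cancer", "cancer", config.n_single_cancer),
        ("CID", "CID", config.n_cid_tracked),
        ("CID", "NK", config.n_killed),
    ]
    start, end = [], []
    for s, e, n in blocks:
        start += [s] * n
        end += [e] * n
    total = len(start)
    ids = [f"CH{i + 1:04d}" for i in range(total)]
    return pd.DataFrame(
        {"chamber_id": ids, "start_composition": start, "end_composition": end}
    )


def _doublet_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """(tracked non-killing CID ids, killing CID ids)."""
    layout = _chamber_layout(config)
    cid = layout.chamber_id[
        (layout.start_composition == "CID") & (layout.end_composition == "CID")
    ].tolist()
    killed = layout.chamber_id[
        (layout.start_composition == "CID") & (layout.end_composition == "NK")
    ].tolist()
    return cid, killed


# ---------------------------------------------------------------------------
# ground truth


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted structure: gene roles, half-lives, peaks, LR pairs,
    kill times."""
    rng = _rng(config, _STREAM_TRUTH)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor:cursor + n]
        if len(block) < n:
            raise ConfigurationError("n_genes too small for the planted gene roles")
        cursor += n
        return block

    nk_markers = take(config.n_marker_genes)
    cancer_markers = take(config.n_marker_genes)

    module_membership: dict[str, str] = {}
    peak_hour: dict[str, int] = {}
    coupling_sign: dict[str, int] = {}
    peaks = config.peak_hours()
    signs = config.coupling_signs()
    for m, (size, peak, sign) in enumerate(
            zip(config.module_sizes, peaks, signs), start=1):
        for g in take(size):
            module_membership[g] = f"M{m}"
            peak_hour[g] = int(peak)
            coupling_sign[g] = int(sign)

    de_genes = {g: float(config.de_log2fc) for g in take(config.n_de_genes)}

    n_pairs = config.n_lr_pairs_coordinated + config.n_lr_pairs_null
    lr_genes = take(2 * n_pairs)
    pairs = [(lr_genes[2 * i], lr_genes[2 * i + 1]) for i in range(n_pairs)]
    coordinated = pairs[: config.n_lr_pairs_coordinated]
    null = pairs[config.n_lr_pairs_coordinated:]

    # half-lives: log-normal around the module / background medians
    half_life: dict[str, float] = {}
    module_set = set(module_membership)
    ln_sd = config.halflife_log_sd
    draws = rng.lognormal(mean=0.0, sigma=ln_sd, size=config.n_genes)
    for g, u in zip(genes, draws):
        med = (config.halflife_module_mean if g in module_set
               else config.halflife_background_mean)
        half_life[g] = float(med * u)

    _, killed_ids = _doublet_ids(config)
    kill_hours = {}
    if killed_ids:
        lo = 2
        hi = max(lo + 1, config.n_timepoints - 1)  # leave at least one missing frame
        hours = rng.integers(lo, hi + 1, size=len(killed_ids))
        kill_hours = {c: int(h) for c, h in zip(killed_ids, hours)}

    return GroundTruth(
        genes=genes,
        module_membership=module_membership,
        half_life=half_life,
        peak_hour=peak_hour,
        coupling_sign=coupling_sign,
        coordinated_pairs=coordinated,
        null_pairs=null,
        kill_hours=kill_hours,
        de_genes=de_genes,
        nk_markers=nk_markers,
        cancer_markers=cancer_markers,
    )


# ---------------------------------------------------------------------------
# manifest


def simulate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Chamber manifest with start/end composition, batch id and sequenced flag.

    The composition reproduces the emulated run: 4 chambers empty throughout,
    8 cancer->empty, 10 NK->empty, 2 NK-start doublets, 22 doublet->cancer
    (all later excluded), plus retained NK and cancer singlets, tracked
    doublets and killing-event doublets. Which tracked doublets are flagged
    unsequenced is drawn uniformly per seed.
    """
    rng = _rng(config, _STREAM_MANIFEST)
    manifest = _chamber_layout(config)
    manifest["run_id"] = rng.choice(["run1", "run2"], size=len(manifest))
    sequenced = pd.Series(True, index=manifest.index)
    cid_rows = manifest.index[
        (manifest.start_composition == "CID") & (manifest.end_composition == "CID")
    ]
    n_unseq = config.n_cid_tracked - config.n_cid
    if n_unseq > 0:
        unseq = rng.choice(cid_rows, size=n_unseq, replace=False)
        sequenced.loc[unseq] = False
    manifest["sequenced"] = sequenced
    return manifest


# ---------------------------------------------------------------------------
# distances


def _fold(x: np.ndarray, d_max: float) -> np.ndarray:
    """Reflect values into [0, d_max] (billiard reflection)."""
    return d_max - np.abs(d_max - np.mod(x, 2.0 * d_max))


def simulate_distances(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Cell-cell distance trajectories for every tracked doublet.

    A reflected Gaussian random walk in [0, d_max] sampled hourly (frames
    T0..T13) with an additional perturbation jump at the post-medium-exchange
    frames T5p/T10p; the jump persists into the subsequent walk. Killing-event
    doublets lose the cancer cell at their kill hour: all frames from that
    hour onward are missing.

    Returns a DataFrame indexed by chamber id with one column per frame label.
    """
    if truth is None:
        truth = make_ground_truth(config)
    rng = _rng(config, _STREAM_DISTANCES)
    cid_ids, killed_ids = _doublet_ids(config)
    ids = cid_ids + killed_ids
    n = len(ids)
    frames = config.frame_labels

    d = rng.uniform(0.0, config.d_max, size=n)
    values: dict[str, np.ndarray] = {}
    for h in range(config.n_timepoints + 1):
        if h > 0 and config.step_sd > 0:
            d = _fold(d + rng.normal(0.0, config.step_sd, size=n), config.d_max)
        values[f"T{h}"] = d.copy()
        post = f"T{h}p"
        if post in frames:
            if config.exchange_jump_sd > 0:
                d = _fold(d + rng.normal(0.0, config.exchange_jump_sd, size=n),
                          config.d_max)
            values[post] = d.copy()

    table = pd.DataFrame(values, index=pd.Index(ids, name="cid_id"))[frames]

    for chamber, hour in truth.kill_hours.items():
        missing = [f for f in frames if FRAME_HOURS[f] >= hour]
        table.loc[chamber, missing] = np.nan
    return table


# ---------------------------------------------------------------------------
# expression


def _memory_kernel(peak: int, tau: float, hours: np.ndarray) -> np.ndarray:
    """Exponential memory kernel: weight of hour t on the terminal readout.

    Peaks at the gene's activity hour and decays backwards with rate
    ln2 / tau; hours after the peak contribute nothing.
    """
    w = np.exp(-np.clip(peak - hours, 0.0, None) * math.log(2.0) / max(tau, 1e-6))
    w[hours > peak] = 0.0
    return w


def simulate_expression(
    config: SimulationConfig,
    distances: pd.DataFrame,
    truth: GroundTruth,
    manifest: pd.DataFrame | None = None,
    marginal: str = "lognormal",
) -> pd.DataFrame:
    """Terminal gene x cell expression for every chamber library.

    Module genes in doublet chambers couple to the distance history through
    the gene's memory kernel; coordinated ligand-receptor pairs share a latent
    factor across doublet libraries; planted killing-response genes are offset
    in killing chambers; singlet libraries carry lineage-marker offsets.
    Background genes are distance-independent noise.

    ``marginal`` selects the non-negative output mapping: ``"lognormal"``
    exponentiates the latent Gaussian (RSEM-like heavy tail), ``"linear"``
    shifts/scales it and clips at zero (keeps planted couplings exactly
    affine, useful for calibration checks).
    """
    if manifest is None:
        manifest = simulate_manifest(config)
    if marginal not in ("lognormal", "linear"):
        raise ConfigurationError(f"unknown marginal {marginal!r}")

    cid_ids, killed_ids = _doublet_ids(config)
    doublets = cid_ids + killed_ids
    missing_cids = [c for c in doublets if c not in distances.index]
    if missing_cids:
        raise ValueError(
            f"distance table lacks {len(missing_cids)} doublet chambers "
            f"(e.g. {missing_cids[:3]}); expression and distances disagree on the CID set")

    rng = _rng(config, _STREAM_EXPRESSION)
    genes = truth.genes
    cells = manifest.chamber_id.tolist()
    n_g, n_c = len(genes), len(cells)
    gene_ix = {g: i for i, g in enumerate(genes)}
    cell_ix = {c: j for j, c in enumerate(cells)}

    # per-gene baseline on the natural-log scale; LR-pair genes boosted so the
    # pair screen's top-50%-by-mean selection retains them
    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_g)
    lr_genes = {g for p in truth.coordinated_pairs + truth.null_pairs for g in p}
    for g in lr_genes:
        mu[gene_ix[g]] = config.baseline_log_mean + 1.5 + 0.3 * rng.normal()

    signal = np.zeros((n_g, n_c))

    # lineage offsets for singlets (on the latent scale)
    nk_cells = manifest.chamber_id[(manifest.start_composition == "NK")
                                   & (manifest.end_composition == "NK")]
    ca_cells = manifest.chamber_id[(manifest.start_composition == "cancer")
                                   & (manifest.end_composition == "cancer")]
    nk_j = [cell_ix[c] for c in nk_cells]
    ca_j = [cell_ix[c] for c in ca_cells]
    for g in truth.nk_markers:
        signal[gene_ix[g], nk_j] += 3.0
    for g in truth.cancer_markers:
        signal[gene_ix[g], ca_j] += 3.0

    # distance coupling of module genes across doublet chambers
    hours = np.arange(1, config.n_timepoints + 1, dtype=float)
    hour_frames = [f"T{int(h)}" for h in hours]
    dmat = distances.loc[doublets, hour_frames].to_numpy()  # doublets x hours
    observed = ~np.isnan(dmat)
    dz = np.where(observed, dmat, 0.0)
    doublet_j = np.array([cell_ix[c] for c in doublets])
    for g in truth.module_genes():
        w = _memory_kernel(truth.peak_hour[g], truth.half_life[g], hours)
        wsum = (observed * w).sum(axis=1)
        wsum[wsum == 0] = np.nan
        k = (dz * w).sum(axis=1) / wsum           # kernel-weighted distance
        k = np.where(np.isnan(k), 0.0, k)
        sd = k.std()
        kz = (k - k.mean()) / sd if sd > 0 else np.zeros_like(k)
        signal[gene_ix[g], doublet_j] += (
            truth.coupling_sign.get(g, 1) * config.coupling_strength * kz)

    # shared latent factors of coordinated LR pairs (doublet libraries only)
    for ga, gb in truth.coordinated_pairs:
        f = rng.normal(0.0, 1.0, size=len(doublets))
        signal[gene_ix[ga], doublet_j] += config.lr_latent_sd * f
        signal[gene_ix[gb], doublet_j] += config.lr_latent_sd * f

    # killing-response genes: offset in killing chambers on the log2 scale
    kill_j = [cell_ix[c] for c in killed_ids]
    if kill_j and config.latent_scale > 0:
        for g, lfc in truth.de_genes.items():
            signal[gene_ix[g], kill_j] += lfc * math.log(2.0) / config.latent_scale

    noise = rng.normal(0.0, config.noise_sd, size=(n_g, n_c))
    latent = mu[:, None] + config.latent_scale * (signal + noise)

    if marginal == "lognormal":
        x = np.exp(latent)
    else:
        x = np.clip(latent, 0.0, None)
    return pd.DataFrame(x, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(cells, name="cell"))


def simulate_channels(config: SimulationConfig,
                      manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Two staining-channel intensity columns per chamber (NK dye, cancer dye)."""
    if manifest is None:
        manifest = simulate_manifest(config)
    rng = _rng(config, _STREAM_CHANNELS)
    has_nk = (manifest.start_composition.isin(["NK", "CID"])).to_numpy()
    has_ca = (manifest.start_composition.isin(["cancer", "CID"])).to_numpy()
    n = len(manifest)
    nk = 2.0 + 4.0 * has_nk + rng.normal(0, 0.8, n)
    ca = 2.0 + 4.0 * has_ca + rng.normal(0, 0.8, n)
    return pd.DataFrame({"cell_id": manifest.chamber_id,
                         "nk_channel": nk, "cancer_channel": ca})


# ---------------------------------------------------------------------------
# ancillary tables


def simulate_lr_inputs(
    config: SimulationConfig,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ligand-receptor pair database and mRNA half-life table.

    The pair database mixes coordinated and null pairs in shuffled order with
    free-text categories. The half-life table covers ``halflife_coverage`` of
    all genes, so downstream joins must handle missing genes.
    """
    rng = _rng(config, _STREAM_LR)
    categories = ["cytokine", "checkpoint", "growth factor", "other"]
    pairs = list(truth.coordinated_pairs) + list(truth.null_pairs)
    rows = [
        {"gene_A": a, "gene_B": b, "category": categories[i % len(categories)]}
        for i, (a, b) in enumerate(pairs)
    ]
    lr = pd.DataFrame(rows, columns=["gene_A", "gene_B", "category"])
    if len(lr) > 1:
        lr = lr.iloc[rng.permutation(len(lr))].reset_index(drop=True)

    n_cov = int(round(config.halflife_coverage * config.n_genes))
    covered = sorted(rng.choice(truth.genes, size=n_cov, replace=False))
    hl = pd.DataFrame({
        "gene": covered,
        "half_life_hours": [truth.half_life[g] for g in covered],
    })
    return lr, hl


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedBundle:
    """All five pipeline inputs plus channels and ground truth."""

    config: SimulationConfig
    manifest: pd.DataFrame
    distances: pd.DataFrame
    expression: pd.DataFrame
    lr_pairs: pd.DataFrame
    halflife: pd.DataFrame
    channels: pd.DataFrame
    truth: GroundTruth = field(repr=False)


def simulate_all(config: SimulationConfig, marginal: str = "lognormal") -> SimulatedBundle:
    """Generate a complete, mutually consistent experiment."""
    truth = make_ground_truth(config)
    manifest = simulate_manifest(config)
    distances = simulate_distances(config, truth)
    expression = simulate_expression(config, distances, truth, manifest, marginal)
    lr_pairs, halflife = simulate_lr_inputs(config, truth)
    channels = simulate_channels(config, manifest)
    return SimulatedBundle(config, manifest, distances, expression,
                           lr_pairs, halflife, channels, truth)


def write_bundle(bundle: SimulatedBundle, outdir, mtx: bool = False) -> dict[str, str]:
    """Write every input table to ``outdir``; returns name -> path."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["manifest"] = str(outdir / "manifest.tsv")
    bundle.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    paths["expression"] = str(outdir / "expression.tsv")
    _io.write_expression_tsv(bundle.expression, paths["expression"])
    if mtx:
        paths["expression_mtx"] = str(outdir / "expression.mtx")
        _io.write_expression_mtx(bundle.expression, outdir / "expression.mtx")
    paths["distances"] = str(outdir / "distances.csv")
    bundle.distances.to_csv(paths["distances"])
    paths["halflife"] = str(outdir / "halflife.tsv")
    bundle.halflife.to_csv(paths["halflife"], sep="\t", index=False)
    paths["lr_pairs"] = str(outdir / "lr_pairs.tsv")
    bundle.lr_pairs.to_csv(paths["lr_pairs"], sep="\t", index=False)
    paths["channels"] = str(outdir / "channels.tsv")
    bundle.channels.to_csv(paths["channels"], sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.json")
    Path(paths["truth"]).write_text(bundle.truth.to_json())
    return paths
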