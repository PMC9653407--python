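"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """An invalid parameter value in a simulation or pipeline configuration."""


# 16 imaging frames: hourly T0..T13 plus a post-medium-exchange duplicate at
# hours 5 and 10 (T5p, T10p taken immediately after the exchange).
FRAME_LABELS: tuple[str, ...] = (
    "T0", "T1", "T2", "T3", "T4", "T5", "T5p",
    "T6", "T7", "T8", "T9", "T10", "T10p", "T11", "T12", "T13",
)

#: hour of each frame (duplicate frames share the hour of their exchange)
FRAME_HOURS: dict[str, int] = {
    lab: int(lab[1:].rstrip("p")) for lab in FRAME_LABELS
}

EXCHANGE_FRAMES: tuple[str, str] = ("T5p", "T10p")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic doublet-tracking experiment.

    Defaults reproduce the study conditions of the emulated experiment: a
    336-chamber run with 77 NK singlets, 71 cancer singlets, 132 tracked
    cancer-NK doublets (CIDs, 102 of them sequenced), 10 killing events, and
    hourly distance imaging over 13 h with medium exchange at hours 5 and 10.

    Parameters
    ----------
    seed
        Base seed; every random stream derives from it.
    n_cid
        Number of sequenced (transcriptome-profiled) non-killing CIDs among
        the tracked doublets.
    n_cid_tracked
        Total non-killing doublets tracked by imaging.
    n_killed
        Doublets in which the NK cell lyses the cancer cell; their distance
        trajectory is missing from the kill hour onward and their terminal
        library is NK-only.
    n_genes
        Genes in the simulated expression matrix.
    module_sizes
        Sizes of the planted distance-coupled gene modules; each module has
        its own memory-peak timepoint.
    n_timepoints
        Hourly distance timepoints after T0 (13 gives frames T0..T13).
    d_max
        Chamber-scale upper bound on cell-cell distance, in µm.
    step_sd
        Per-hour standard deviation of the reflected Gaussian random walk,
        µm. 25 µm on an 80 µm chamber decorrelates trajectories on the
        hour scale, so module peak times are temporally resolvable.
    exchange_jump_sd
        Extra displacement (µm) applied at the post-exchange frames T5p/T10p;
        the perturbation persists into the subsequent walk.
    coupling_strength
        Dimensionless scale of the distance -> expression coupling of module
        genes.
    noise_sd
        Standard deviation of the per-gene latent Gaussian noise (latent
        log-expression scale).
    latent_scale
        Multiplier taking the standardized latent signal onto the natural-log
        expression scale before exponentiation.
    baseline_log_mean, baseline_log_sd
        Per-gene baseline of the log-normal expression marginal.
    halflife_module_mean, halflife_background_mean
        Median mRNA half-life (hours) of module and background genes; module
        genes are drawn with the longer half-life, which also sets their
        memory-kernel decay.
    halflife_log_sd
        Log-scale spread of the half-life distributions.
    halflife_coverage
        Fraction of genes present in the emulated half-life resource (the
        join downstream must tolerate missing genes).
    n_lr_pairs_coordinated, n_lr_pairs_null
        Ligand-receptor pairs with / without an injected shared latent factor
        across doublet libraries.
    lr_latent_sd
        Scale of the shared latent factor of coordinated pairs.
    n_de_genes, de_log2fc
        Genes upregulated in killing (NK-only terminal) doublets and their
        planted log2 fold change.
    n_marker_genes
        Lineage marker genes per singlet cell type (offset applied to the
        corresponding singlets).
    """

    seed: int = 0
    n_cid: int = 102
    n_cid_tracked: int = 132
    n_single_nk: int = 77
    n_single_cancer: int = 71
    n_killed: int = 10
    # excluded-chamber composition of the emulated run
    n_empty: int = 4
    n_cancer_to_empty: int = 8
    n_nk_to_empty: int = 10
    n_nk_start_cid: int = 2
    n_cid_to_cancer: int = 22
    n_genes: int = 3000
    module_sizes: Sequence[int] = field(default_factory=lambda: [30, 25, 20, 15])
    module_peak_hours: Sequence[int] | None = None
    module_signs: Sequence[int] | None = None
    n_timepoints: int = 13
    d_max: float = 80.0
    step_sd: float = 25.0
    exchange_jump_sd: float = 20.0
    coupling_strength: float = 1.0
    noise_sd: float = 1.0
    latent_scale: float = 0.5
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.8
    halflife_module_mean: float = 2.0
    halflife_background_mean: float = 1.0
    halflife_log_sd: float = 0.5
    halflife_coverage: float = 0.7
    n_lr_pairs_coordinated: int = 8
    n_lr_pairs_null: int = 40
    lr_latent_sd: float = 1.5
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    n_marker_genes: int = 20

    def __post_init__(self) -> None:
        self.module_sizes = list(self.module_sizes)
        counts = {
            "n_cid": self.n_cid,
            "n_cid_tracked": self.n_cid_tracked,
            "n_single_nk": self.n_single_nk,
            "n_single_cancer": self.n_single_cancer,
            "n_genes": self.n_genes,
            "n_timepoints": self.n_timepoints,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        for name in ("n_killed", "n_empty", "n_cancer_to_empty", "n_nk_to_empty",
                     "n_nk_start_cid", "n_cid_to_cancer", "n_lr_pairs_coordinated",
                     "n_lr_pairs_null", "n_de_genes", "n_marker_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_cid > self.n_cid_tracked:
            raise ConfigurationError(
                f"n_cid ({self.n_cid}) cannot exceed n_cid_tracked ({self.n_cid_tracked})")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module_sizes must all be > 0")
        if sum(self.module_sizes) >= self.n_genes:
            raise ConfigurationError("module_sizes must sum to less than n_genes")
        if self.d_max <= 0:
            raise ConfigurationError(f"d_max must be > 0, got {self.d_max}")
        if self.step_sd < 0 or self.exchange_jump_sd < 0:
            raise ConfigurationError("step_sd and exchange_jump_sd must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.halflife_module_mean <= 0 or self.halflife_background_mean <= 0:
            raise ConfigurationError("half-life means must be > 0")
        if not 0 <= self.halflife_coverage <= 1:
            raise ConfigurationError("halflife_coverage must be in [0, 1]")
        if self.module_peak_hours is not None:
            self.module_peak_hours = list(self.module_peak_hours)
            if len(self.module_peak_hours) != len(self.module_sizes):
                raise ConfigurationError(
                    "module_peak_hours must match module_sizes in length")
            if any(not 1 <= h <= self.n_timepoints for h in self.module_peak_hours):
                raise ConfigurationError("module peak hours must lie in [1, n_timepoints]")
        if self.module_signs is not None:
            self.module_signs = list(self.module_signs)
            if len(self.module_signs) != len(self.module_sizes):
                raise ConfigurationError(
                    "module_signs must match module_sizes in length")
            if any(s not in (-1, 1) for s in self.module_signs):
                raise ConfigurationError("module_signs entries must be +1 or -1")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def frame_labels(self) -> list[str]:
        """Imaging frame labels, hourly plus post-exchange duplicates."""
        labels = [f"T{h}" for h in range(self.n_timepoints + 1)]
        out: list[str] = []
        for lab in labels:
            out.append(lab)
            h = int(lab[1:])
            if h in (5, 10) and h < self.n_timepoints:
                out.append(f"T{h}p")
        return out

    def coupling_signs(self) -> list[int]:
        """Coupling sign of each module: proximity can induce or repress a
        module, so signs alternate +1, -1, ... unless given explicitly."""
        if self.module_signs is not None:
            return list(self.module_signs)
        return [1 if i % 2 == 0 else -1 for i in range(self.n_modules)]

    def peak_hours(self) -> list[int]:
        """Memory-peak hour of each module (evenly spread if not given)."""
        if self.module_peak_hours is not None:
            return list(self.module_peak_hours)
        k = self.n_modules
        if k == 1:
            return [self.n_timepoints]
        lo, hi = 2, self.n_timepoints
        return [round(lo + i * (hi - lo) / (k - 1)) for i in range(k)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
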