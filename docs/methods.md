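# Methods

## The analysis model

A cancer–immune doublet (CID) is one NK cell and one cancer cell co-incubated
in a microfluidic chamber for 13 h with hourly imaging and medium exchange at
hours 5 and 10 (each exchange hour is imaged twice, just before and just
after the exchange, so 16 frames cover the hourly labels T0..T13 plus T5′ and
T10′). Each chamber yields a single terminal RSEM-style expression library;
distances are the membrane-to-membrane separation in µm.

The pipeline's stages, in order:

1. **Chamber classification.** Each chamber's start/end composition maps to
   exactly one category. Chambers that start empty, lose their only cell
   (cancer→empty, NK→empty), start as a single NK cell but end as a doublet,
   or collapse from a doublet to a cancer singlet are excluded. Retained
   categories: NK singlet, cancer singlet, tracked doublet (CID), and
   doublet-ending-NK-only (`CID_NK_only`, a killing event). On the standard
   336-chamber composition this excludes 46 and retains 290 libraries.
2. **QC filters.** Cells with fewer than 2000 expressed genes (strictly
   positive values) are dropped, then genes with expression > 5 in fewer than
   10 cells. Boundary semantics are literal: "fewer than 2000" is strict,
   "> 5" is strict, "at least 10" is inclusive. The order (cells first) is
   part of the contract and recorded in provenance; filters are idempotent.
3. **Correlation map.** For the sequenced tracked doublets, the top-2000
   variable genes (sample variance of log(1+x); ties broken by gene id) are
   correlated against the distance at each analysis timepoint:
   `rho[g, t]` is the Pearson correlation across doublets, computed over
   pairwise-complete observations (killing events truncate trajectories).
   Entries with fewer than `n_min = 5` complete pairs or zero variance are
   missing. The default timepoint policy uses the 13 hourly frames T1..T13
   with the *pre*-exchange image at exchange hours; post-exchange and
   include-T0 policies are configurable and recorded in provenance.
4. **Memory genes and modules.** Genes with `|rho| >= 0.25` at one or more
   timepoints are retained (inclusive threshold, monotone in the cutoff) and
   clustered by average-linkage hierarchical clustering on the Euclidean
   distance between rho rows, cut at exactly k = 4. Missing rho entries are
   imputed as 0 *for clustering only* (count recorded). Modules are renamed
   M1..Mk by the hour at which the cluster-mean |rho| peaks (M1 earliest), so
   labels are stable across runs; the underlying heatmap ordering of any
   particular dataset carries no information the labels depend on.
5. **Half-life association.** Module genes are joined (case-normalized inner
   join) against an mRNA half-life table in hours (minute-scale tables are
   converted via a declared flag); module vs background half-lives are
   compared with a two-sided Welch two-sample t-test (Welch–Satterthwaite
   degrees of freedom). The default background is *half-life-table genes not
   in the modules*; an alternative "universe" mode restricts the background
   to a supplied gene set first. If both groups have zero variance and equal
   means the test is declared uninformative (t = 0, p = 1); zero variance
   with unequal means is rejected as degenerate input rather than reported
   as an infinitely significant result.
6. **Ligand–receptor screen.** Genes are ranked by mean expression across
   *all* retained cells and the top 50 % kept; database pairs with both genes
   selected become candidates. For each candidate and each cell group
   (doublets, killing doublets, NK singlets, cancer singlets with >= n_min
   cells) the pair's Pearson correlation is computed. A pair qualifies when
   its correlation in the main doublet group is strictly above 0.4 *and* no
   singlet group exceeds the same bar — co-expression explainable by one cell
   type alone is not evidence of cross-cell signaling. The killing-doublet
   group (n = 10) is always reported but never decides qualification: ten
   observations cannot support a stable correlation estimate. All per-group
   values are emitted so users can apply alternative rules.
7. **Killing differential expression.** Killing vs non-killing doublets are
   contrasted per gene by a Welch t-test on log2(1 + x) (pseudocount 1 on the
   RSEM scale), BH-adjusted across tested genes; significance requires
   adjusted p < 0.05 and |log2FC| >= 1. This engine is a deliberately simple,
   clearly labelled stand-in for moderated-model packages: the decision
   thresholds, not the test engine, are the specified analysis surface, and
   gene lists from real data will differ between engines. Genes flat in both
   groups are excluded from testing and reported. Up/down signature lists are
   exported for external survival tools; no survival analysis is performed.

## The synthetic-data generator

The generator emulates the five pipeline inputs under the study conditions:
336 chambers in the printed composition (4 empty, 8 cancer→empty, 10
NK→empty, 2 NK-start doublets, 22 doublet→cancer, 77 NK singlets, 71 cancer
singlets, 132 tracked doublets of which 102 are flagged sequenced, 10 killing
events), 13 hourly timepoints with exchange duplicates, 3000 genes with 90
planted module genes in four modules (30/25/20/15).

**Distances** follow a reflected Gaussian random walk in [0, d_max = 80 µm]
with per-hour step SD 25 µm, plus an additional jump (SD 20 µm) at the
post-exchange frames whose displacement persists into the subsequent walk.
The experiment reports no distance dynamics model, so the walk is the
minimal-assumption choice; the step size is set large enough that
trajectories decorrelate on the hour scale — without that, distances at
neighbouring hours are nearly collinear and no method could resolve *when* a
memory gene was coupled, only *that* it was. Killing-event doublets get a
kill hour drawn uniformly in [2, 12]; all frames from that hour onward are
missing.

**Expression.** A module gene g with activity peak t*_g and mRNA half-life
τ_g couples to the kernel-weighted distance history

```
w_g(t) = exp(-(t*_g - t) · ln 2 / τ_g)   for t <= t*_g,   0 afterwards
```

so a long-lived transcript integrates distances far back from its peak —
the mechanistic reading of half-life-dependent transcriptional memory. The
standardized kernel average enters a per-gene latent Gaussian (coupling
strength 1, noise SD 1, latent scale 0.5) on top of a log-normal baseline,
and values are exponentiated to an RSEM-like non-negative marginal (an
alternative shifted-linear marginal, clipped at zero, keeps planted couplings
exactly affine and is used in calibration tests). Module peaks are spread
over the schedule (hours 2, 6, 9, 13 for four modules) and modules alternate
coupling sign — proximity induces some programs and represses others, which
matches a two-sided correlation map and keeps adjacent-peak modules
geometrically separable. Module half-lives are log-normal with median 2 h vs
1 h for background (log-SD 0.5), giving the Welch stage a planted but not
overwhelming shift. Killing chambers carry 40 genes offset by log2FC = 2;
NK/cancer singlets carry 20 lineage-marker offsets each; coordinated
ligand–receptor pairs (8, plus 40 null pairs) share a latent factor of SD 1.5
across doublet libraries only, giving pair correlations ≈ 0.6 in doublets
and ≈ 0 in singlets. Ligand–receptor genes get boosted baselines so the
top-50 %-by-mean selection retains them; the half-life table covers 70 % of
genes so joins must handle missing entries.

**What the generator does not emulate:** count noise and dropout structure of
real libraries, batch effects between runs (the pipeline accepts a
pre-corrected matrix and records a `batch_corrected` flag instead of
reimplementing anchor-based integration), ambient RNA, cell-cycle structure,
or any real gene identity. Passing recovery tests therefore demonstrates
that the statistics detect the structure they are designed for at realistic
sample sizes — not that real chamber data contain that structure, nor that
the printed gene counts of any particular experiment will reproduce.

## Numerical and design choices

- **Pearson implementation**: centred dot products with explicit zero-variance
  guards; values clipped to [-1, 1]; verified against an elementwise
  textbook-formula oracle to 1e-10 and affine-invariant to 1e-10.
- **|T| ambiguity**: the imaging schedule yields 16 frames and 14 hourly
  labels; the declared default analyses the 13 frames T1..T13 (pre-exchange
  at exchange hours). T0 is the pre-incubation baseline and is excluded by
  default; both alternatives are one config switch away and recorded in
  provenance.
- **Variable-gene statistic**: plain log1p-scale variance rather than a
  fitted mean–variance trend; the selection a published package would make
  is not recoverable from defaults, so a simple documented statistic with
  deterministic tie-breaking (rank, then gene id) is preferred.
- **Clustering**: average linkage on Euclidean distance; only the tree-cut
  count (4) is inherent to the analysis, so linkage and metric are exposed
  as parameters and recorded in provenance.
- **Protein-coding restriction** is an optional allow-list file; no
  annotation source is bundled, so the post-filter gene count is
  data-dependent, not a contract.
- **Degenerate inputs**: empty manifests classify to an empty report; an
  all-missing distance table is fatal (< 3 complete pairs); unclassifiable
  chamber compositions and unknown composition labels raise errors naming
  the offending row rather than guessing.
- **Determinism**: every random stream derives from the config seed through
  named substreams, so each generator stage is reproducible standalone; a
  pipeline run is byte-identical under a fixed config (content hashes in
  `output_manifest.json`), and the report is a pure function of the saved
  outputs.
- **Problem sizes in tests**: recovery and calibration tests run the full
  336-chamber / 3000-gene conditions over 20 replicate simulations, and the
  permutation-null calibration uses 60 label permutations; these sizes give
  stable metrics while keeping the suite fast.

## Known limitations

- The doublet library is the chamber's joint transcriptome; no deconvolution
  into NK and cancer contributions is attempted, so "doublet-specific
  co-expression" conflates cross-cell signaling with within-chamber
  composition effects — exactly why the singlet rule-out exists.
- The Welch/BH differential-expression engine has no precision weights or
  variance moderation; with 10 killing doublets its gene lists are noisier
  than a moderated engine's would be.
- The background false-retention rate of the |rho| >= 0.25 rule at |C| = 102
  is ~10 % of genes across 13 correlated timepoints; the retained set of any
  single run mixes true memory genes with that background, which is why
  module-level (not per-gene) conclusions are the supported output.
- Half-life values are borrowed from a different cell line in the emulated
  resource; the association test inherits that approximation.
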