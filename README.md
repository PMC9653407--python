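# cidmem

Doublet-resolution analysis linking the *time course of cancer–immune cell
proximity* to *terminal single-cell transcriptomes*.

## The scientific problem

When a natural killer (NK) cell and a cancer cell are co-incubated in a
microfluidic chamber, their physical distance fluctuates over hours while
their transcriptomes evolve. Sequencing destroys the cells, so expression can
only be read once — at the end. The question this package addresses: does the
terminal transcriptome of such a cancer–immune doublet (CID) still carry a
trace of *earlier* cell–cell distances, i.e. does transcriptional memory
exist, and is it carried by slowly degrading (long half-life) mRNAs?

The package is written for computational biologists analysing chamber-based
doublet experiments: a manifest of chamber compositions, a terminal RSEM-style
gene × cell expression matrix, an hourly cell–cell distance table (with
pre/post medium-exchange duplicate frames), an mRNA half-life resource, and a
ligand–receptor pair database.

## The core statistic

With the processed expression matrix `E` (|G| genes × |C| doublets) and the
distance matrix `D` (|C| doublets × |T| hourly timepoints), the pipeline
computes the gene × timepoint Pearson map

```
rho[g, t] = corr( E[g, ·], D[·, t] )        over pairwise-complete doublets
```

Genes with `max_t |rho[g, t]| >= 0.25` are retained as *memory genes* and
partitioned into modules by hierarchical clustering of their `rho` rows
(average linkage, Euclidean metric, tree cut at k = 4); modules are named
M1..M4 by the hour at which their mean |rho| peaks. Downstream stages test
whether module genes have longer mRNA half-lives than background genes (Welch
two-sample t-test), screen ligand–receptor pairs for doublet-specific
co-expression (pair correlation > 0.4 in doublets but not in either singlet
type alone), and contrast killing-event doublets (NK-only at the terminal
timepoint) against surviving doublets (Welch on log2(1+x), BH adjustment,
significance at adjusted p < 0.05 and |log2FC| >= 1).

Because the raw chamber data are not bundled, a first-class synthetic
generator (`cidmem.simulate`) emulates all five inputs with planted ground
truth: distance-coupled gene modules whose memory kernel decays with each
gene's mRNA half-life, coordinated ligand–receptor pairs, killing events and
the standard 336-chamber composition.

## Worked example

```python
from cidmem import (SimulationConfig, classify_chambers, align_inputs,
                    select_variable_genes, correlate_distance_expression,
                    select_memory_genes, cluster_modules, timepoint_policy,
                    module_halflife_report)
from cidmem.simulate import simulate_all

bundle = simulate_all(SimulationConfig(seed=1))
classified, report = classify_chambers(bundle.manifest)
print(report["n_total"], report["n_excluded"], report["n_retained"])
# 336 46 290          <- 4+8+10+2+22 chambers excluded; 77 NK, 71 cancer,
#                        132 tracked doublets, 10 killing events retained

aligned = align_inputs(bundle.expression, bundle.distances, classified)
print(aligned.n_cid)                     # 102 sequenced doublets
tps = timepoint_policy(aligned.distances.columns)
hvg = select_variable_genes(aligned.expression, 2000)
corr = correlate_distance_expression(aligned.expression.loc[hvg],
                                     aligned.distances, tps)
memory = select_memory_genes(corr, 0.25)
print(corr.rho.shape, len(memory))       # (2000, 13) 311
modules = cluster_modules(corr, memory, k=4)
hl = module_halflife_report(memory, bundle.halflife)
print(hl["n_matched"], round(hl["welch"]["p"], 7))
# 228 9.71e-05        <- matched module genes live longer than background
```

The numbers mean: of 336 chamber libraries, 46 are excluded by the
composition rules and 290 retained; 102 sequenced doublets enter the 2000-gene
× 13-timepoint correlation map; 311 genes clear the |rho| >= 0.25 memory rule
(the 90 planted module genes plus distance-correlated background); and the
half-life resource covers 228 of them, with module half-lives significantly
longer than background (Welch p ≈ 1e-4) — the planted memory mechanism is
recovered.

The same analysis runs from the shell:

```bash
cidmem simulate --outdir data --seed 1
cidmem run --config run.yaml --outdir out     # paths + thresholds in YAML
```

producing `rho_matrix.tsv`, `memory_genes.txt`, `modules.tsv`, a module
heatmap, the half-life report and boxplot, `lr_results.tsv`, `de_results.tsv`,
signature gene lists, provenance with content hashes, and `report.md`.

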