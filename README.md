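# bilayernet

Bilayer DNA-methylation-site/RNA network analysis for tumor epigenomics.

## The problem

Co-methylation networks link CpG probes whose β values (methylated/total
intensity ratio, in [0, 1]) correlate strongly across tumor samples. But CpG
sites do not physically interact: a strong correlation may reflect a shared
regulatory program — or nothing at all. `bilayernet` implements a bilayer
construction that keeps a correlation edge only when the *genes* the two
sites sit on are plausibly coupled in an RNA interaction network, then mines
the filtered layer for hub sites and asks whether those hubs carry
prognostic and transcriptional signal.

The pipeline:

1. **Differential screening.** Sites differing between tumor and normal
   tissue are selected with an empirical-Bayes moderated t-test
   (Benjamini–Hochberg FDR < 0.01). These form the node universe.
2. **Methylation layer.** Sites i, j are linked when the Pearson
   correlation of their β values over tumor samples satisfies |r| > 0.8.
3. **RNA layer.** An undirected graph of RNA–RNA interactions with
   confidence > 0.75 (mRNAs bridged by noncoding RNAs).
4. **Inter-layer edge filter.** A methylation edge survives only if its
   sites (i) share a gene, (ii) sit on genes joined by an RNA-layer edge, or
   (iii) sit on genes sharing an RNA-layer neighbor (distance 2, typically
   through a lncRNA/miRNA bridge). Everything else is removed, however
   strong the correlation. The unfiltered graph is kept as the
   "single-network" baseline.
5. **Hub mining.** Degree centrality DC(v) = deg(v)/(N−1) and unnormalized
   betweenness centrality BC(v) = Σ_{s<t} σ_st(v)/σ_st rank the sites;
   the top-k (k = 100…500) are the hubs.
6. **Evaluation.** Per hub: Kaplan–Meier curves for patients split at the
   site's mean β, compared by the Mantel–Cox log-rank test (p < 0.05 ⇒
   survival-associated); a 2×2 χ² test (df = 1, no continuity correction)
   compares survival-hub counts between the bilayer and single networks;
   hubs are flagged when their genes reach a differentially expressed gene
   (FDR < 0.05, |log2FC| > 1) within two RNA-layer steps; hub comethylation
   is summarised overall and within same-gene groups; hub-specific genes are
   tested for gene-set over-representation with the hypergeometric upper
   tail.

A synthetic-data generator with planted comethylation modules, an
ncRNA-bridged RNA layer, planted DEGs and hazard-coupled hub methylation
makes the whole pipeline testable without any external download.

## Worked example

Run the full pipeline on the bundled synthetic dataset (seed 1):

```bash
bilayernet run --out runs/demo --seed 1
```

or from Python:

```python
from bilayernet import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(simulate=SimulationConfig(seed=1), seed=1, k_list=(100,))
results = run_pipeline(config, "runs/demo")
```

Headline numbers this produces (also written to `runs/demo/*.json`):

| quantity | value | meaning |
|---|---|---|
| differential site recovery | 100.0 % | of 500 planted differential sites pass FDR < 0.01 |
| DEG recovery | 100.0 % | of 30 planted fold-changes pass the DEG thresholds |
| hub-module recovery (top-100 degree) | 100.0 % | planted hub-module sites found among the top-100 degree hubs |
| survival-hub count, bilayer vs single (degree, top-100) | 99 vs 1 | the filter removes the spurious high-degree modules, so prognostic hubs surface |
| χ² for that comparison | 192.1 | p ≈ 1e-43 |
| same-gene hub mean \|r\| vs overall | 0.867 vs 0.095 | sites on one gene co-methylate far more strongly than hubs at large |
| two-step DEG coverage of top-100 bilayer hubs | 100 % | every bilayer hub gene reaches a DEG through ≤ 2 RNA-layer steps |

The single network's top-100 degree hubs are dominated by the planted
RNA-inconsistent modules (strongly correlated, biologically empty), which
carry no survival signal — the bilayer filter is what removes them.

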