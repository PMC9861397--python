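# Methods

## The bilayer model

The object of study is a pair of coupled graphs. The *methylation layer*
has CpG probes as nodes; an edge joins sites i and j when the Pearson
correlation r_ij of their β values across tumor samples exceeds 0.8 in
absolute value (strict inequality; a correlation-coefficient cutoff rather
than a p-value cutoff, because correlation p-values scale with sample size
while the coefficient does not). The *RNA layer* has mRNAs and noncoding
RNAs as nodes, joined when an interaction is supported with confidence
above 0.75 (strict). Inter-layer links connect each probe to the gene(s) it
is annotated to.

A methylation edge is *admissible* when some annotated gene pair
(g_i, g_j) across its two sites satisfies one of three conditions, reported
with precedence in this order:

1. `same_gene` — g_i = g_j;
2. `direct_edge` — (g_i, g_j) is an RNA-layer edge;
3. `shared_neighbor` — g_i and g_j have a common RNA-layer neighbor.

Conditions 2–3 jointly mean RNA-layer distance ≤ 2. Distance exactly 2 is
deliberately the boundary: in real interactomes direct mRNA–mRNA contacts
are rare and most mRNA pairs are coupled through one noncoding bridge, so
allowing one intermediate captures the biologically supported couplings
without admitting the whole component. Inadmissible edges are deleted;
nodes are never deleted, so the node universe is identical between the
filtered ("bilayer") and unfiltered ("single") graphs and top-k hub lists
are comparable. With many-to-many probe annotation, an edge is admissible
if *any* gene pair passes (the most permissive reading; the admitting
condition is recorded per edge).

Only sites that are differentially methylated (moderated t, BH FDR < 0.01)
enter either graph — the network is a model of tumor-perturbed
comethylation, not of the full array.

## Statistical components

**Moderated t.** For feature g with pooled two-group variance s_g² on d
residual degrees of freedom, the posterior variance is
(d₀·s₀² + d·s_g²)/(d₀ + d) and the statistic uses d₀ + d degrees of
freedom. The hyperparameters (d₀, s₀²) are estimated by method of moments
on log s_g²: under the scaled-inverse-χ² prior, s_g²/s₀² ~ F(d, d₀), so
Var[log s_g²] = ψ′(d/2) + ψ′(d₀/2) and d₀ follows by trigamma inversion
(Newton). When the observed variance of log s_g² does not exceed ψ′(d/2)
the prior degrees of freedom are effectively infinite; the code then uses
the analytic limit log s₀² = mean(log s_g²) − ψ(d/2) + log(d/2) and a t
reference with very large df. A zero pooled variance (degenerate inputs) is
floored at 10⁻³ × the smallest positive variance; features constant at the
same value in both groups get p = 1.

**Differential thresholds.** Sites: FDR < 0.01, tested on the β scale
directly (the data's natural scale; M-values would change borderline calls
but not the planted-structure results here). Genes: FDR < 0.05 on
log2(x+1)-transformed expression *and* |log2FC| > 1, with the fold change
computed from raw group means with a pseudo-count of 1 to guard zero means.

**Survival.** Patients are split at the mean β of the site (ties to the
high group); Kaplan–Meier product-limit curves per group; the Mantel–Cox
log-rank χ² with 1 df (via lifelines). "Survival-associated" means
unadjusted p < 0.05 per site — a reproduction convention, not a
recommendation: across hundreds of correlated sites this is an enrichment
screen, not a calibrated discovery procedure.

**2×2 comparison.** Pearson χ² from observed-vs-expected frequencies, df =
1, no continuity correction, on the table (survival-associated / not) ×
(bilayer / single) at equal k. Degenerate tables (a zero column margin,
i.e. no difference to test) return χ² = 0, p = 1 rather than an error when
produced inside the pipeline.

**Enrichment.** Hypergeometric upper tail P(X ≥ k) for a pathway of size K
against an n-gene query over an N-gene background; the default background
is every mRNA in the RNA layer (the only universe the pipeline can know);
flagging uses raw p < 0.05 with BH values reported alongside.

## Network indicators

Degree centrality deg(v)/(N−1); betweenness in the unnormalized endpoint-
excluded form (exact Brandes accumulation, never sampled — rankings are
what matter and they are scale-invariant); clustering C_v = 2E_v/(k_v(k_v−1))
with C_v = 0 for k_v < 2, included in the average by default (configurable).
The average path length is the mean over unordered distinct pairs *within a
connected component*: filtered layers are always disconnected, and
averaging over connected pairs is the only finite convention. The matched
Erdős–Rényi baselines are ln N for path length and ⟨k⟩/(N−1) (the edge
probability) for clustering; ln N, rather than the also-common
ln N/ln⟨k⟩, is the convention this package reports as the random-graph
reference.

## The synthetic-data generator

β values arise from a latent-Gaussian model pushed through the inverse
logit: site i in sample s has latent μ_i + shift + f, with μ_i ~
U(−1.5, 1.5), f built from a module factor (pairwise latent correlation ρ
within a module, independence across modules) plus site noise. This yields
[0, 1]-bounded values with controllable comethylation resembling 450K
array behavior. Differential sites get an additive latent shift (default
1.5, alternating sign by module) in tumor samples only.

Default geometry (2,000 probes, 200 tumor / 50 normal samples, 300 genes):

* 24 *ordinary* admissible modules of 6 sites, ρ = 0.9, cycling through the
  three wiring kinds (one shared gene / two genes with a direct RNA edge /
  two genes sharing an ncRNA bridge);
* 9 *hub* modules of 11 sites, ρ = 0.97 — the planted hubs. Hub modules
  additionally share a common latent process (inter-module factor
  correlation 0.5), modelling a coordinated tumor program: this is what
  makes the mean hub methylation a meaningful per-patient score;
* 7 *inadmissible* modules of 15 sites, ρ = 0.97, each site on its own
  private gene absent from the RNA layer. These are the planted
  confounders: denser and higher-degree than the real hubs, they dominate
  the single network's degree ranking and are entirely removed by the
  filter;
* 25 % of all probes are differential (all module sites, plus background
  singletons up to the fraction).

The RNA layer wires 10 "community" lncRNAs to the module genes of their
community plus one dedicated DEG seed gene each (so every admissible module
gene is ≤ 2 steps from a planted DEG — the structural basis of the
two-step-coverage result), and 50 bulk ncRNAs to random mRNAs with
truncated-power-law degrees (exponent 2.5, range 2–30), giving the
right-skewed, ncRNA-bridged topology of real interactomes. Direct
mRNA–mRNA edges come only from the rna_edge modules (8 of ~700 edges).
Confidences are U(0.7501, 1].

Expression is log-normal (natural-log mean U(3, 7), sd 0.5) with tumor
means multiplied by 2^±2 at the 30 planted DEGs. Survival is exponential
with log-hazard γ·z, where z is the z-scored mean β over all hub-module
sites and γ = 2.5; each hub site correlates ≈ 0.7 with z, so the implied
per-site hazard ratio across a mean-β split is large (≈ e^1.3·…), giving
essentially complete per-site power at n = 200. A 30 % censoring fraction
is applied as uniform-on-(0, T) censoring times. Every generator draws from
its own seed-derived substream, so resizing one table never perturbs the
others; all outputs are bit-reproducible given the seed.

What the generator does *not* emulate: probe-type (Infinium I/II) effects,
batch effects, copy-number confounding, non-exponential hazards,
informative censoring, or realistic annotation ambiguity. Passing tests
demonstrate that the pipeline recovers the structure it models — planted
comethylation, fold changes and hazard coupling — not that real TCGA-scale
data would behave the same way.

## Numerical and design choices

* Probe IDs are case-normalised to lowercase `cg…` (annotation sources are
  inconsistent about capitalisation).
* Thresholds are strict inequalities throughout (|r| > 0.8,
  confidence > 0.75), matching how such cutoffs are stated.
* All-pairs correlation is computed blockwise on z-scored rows (exact
  values, bounded memory; no approximate candidate screening).
* Constant β rows are flagged and can gain no edge (their correlation is
  undefined).
* Hub ties at the top-k boundary break by ascending site ID — stable and
  reproducible.
* Sample-level missingness policy: any probe row containing a missing or
  non-numeric entry is dropped at load time (no imputation); values outside
  [0, 1] are an error, never clipped.
* Duplicate unordered RNA pairs collapse to the maximum confidence;
  self-interactions are dropped.

## Known limitations

* The moderated-t hyperparameter estimator uses the moments of all log
  variances including truly differential features; with very high planted
  effect fractions this slightly inflates s₀².
* Per-site survival calls are correlated within comethylation modules, so
  survival-hub *counts* have module-level, not site-level, sampling
  variance — visible as occasional lucky modules among the null sites.
* The enrichment background is the RNA-layer mRNA universe; results are
  relative to that choice and not comparable across backgrounds.
* At array scale (>10⁵ network nodes) exact betweenness is expensive;
  the implementation stays exact and simply takes the time.
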