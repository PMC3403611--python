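# Methods

## Model

`katznet` prioritizes disease genes by seeded Katz propagation on a weighted
interactome. Let **W** be the symmetric gene–gene weight matrix (entries in
[0, 1], zero diagonal) and **x** the binary activity vector with x_i = 1 for
the seed genes — genes assumed disease-active a priori from causative lists,
proteomics, or differential expression. The score vector solves

    s = x + φ W s    ⇔    s = (I − φ W)⁻¹ x = Σ_{t≥0} φᵗ Wᵗ x,

the Katz resolvent: walks of length *t* from the seeds contribute with
weight φᵗ. Small φ keeps the prior dominant; large φ emphasizes network
coupling. The series converges only for φ < 1/ρ(W), the reciprocal spectral
radius; both solvers check this bound (estimated by 50 power-iteration
steps on the nonnegative symmetric W) and raise a divergence error naming
it otherwise.

Two solvers are provided and tested against each other: a sparse direct
factorization of (I − φW), and Jacobi iteration s⁽ᵗ⁺¹⁾ = x + φWs⁽ᵗ⁾
starting from s⁰ = x, stopping when the max-norm update falls below `tol`
(default 1e-10, max 10 000 iterations; non-convergence raises with the last
residual). Because diag(W) = 0, the Jacobi update coincides with the score
recurrence itself. At the φ values used here (φ·ρ ≤ ~0.25) Jacobi converges
in a few dozen matrix–vector products and is used inside the calibration
loop; single scoring runs use the direct solve.

### Calibrating φ by locus r-ratios

Known causative genes are held out of the seeds. Each held-out gene is
embedded in a candidate set of ~N genes (default N = 100) from its
chromosomal locus — the N genes nearest by interval-midpoint distance on
the same chromosome, the disease gene included; regions smaller than N
contribute all their genes. After scoring with the seeds only, the disease
gene's rank *r* within its candidate set (descending s; ties broken by the
network's stable gene order, the same rule used for global ranks) gives the
r-ratio r/N ∈ (0, 1]. φ* is the grid value minimizing the mean r-ratio over
all held-out genes; the default grid is 30 log-spaced points on [1e-6,
1e-2), and ties go to the smallest φ. After calibration the held-out genes
are added to the seeds and all genes are re-scored at φ*.

On strongly planted synthetic modules the mean r-ratio curve is nearly flat
in φ: one propagation step already separates module genes from locus
background, so every grid value ranks the held-out genes near the top and
the tie rule returns the smallest grid φ. This is expected behavior, not a
calibration failure; the curve is written out so flatness is visible.

### Top fraction, subnetwork, and k-cores

The top ⌈q·D⌉ genes by s-score (default q = 0.10) form the disease gene
set. The denominator D is explicit config: `all_genes` (the whole network)
or `positive_score` (genes reachable from the seeds). The published
analysis reports 380 genes from a 14 532-gene network, which matches
neither reading literally (~2.6 % of all genes), so the mode is a required
choice rather than a guess; `all_genes` is the default.

The disease subnetwork is the subgraph induced by the selected genes,
keeping only edges with weight ≥ 0.5 (the usual medium-confidence cut for
STRING-style scores; configurable). Genes left isolated by the edge filter
are pruned by default — this is how a 380-gene selection can yield a
367-node network — with a flag to keep them.

Topology is summarized by k-core decomposition on unweighted degrees of the
thresholded graph (weights act only at the extraction stage). The k-core is
the maximal subgraph with minimum internal degree k; the layer l_k holds
nodes whose core number is exactly k; the k-core equals the union of layers
j ≥ k. Core numbers come from the standard minimum-degree peeling
(networkx), validated in the tests against an exhaustive
maximal-subgraph-definition oracle on all graphs up to 12 nodes. A
three-way core–periphery partition assigns nodes with core number ≤
k_outer (default 10) to the outer layer, ≤ k_medium (default 35) to the
medium layer, and the rest to the inner core; the cutpoints are config
because they are data-derived in any given study, and no automatic cutpoint
search is attempted. Nodes with core number 0 count as outer.

### Expression screen

Probe-level matrices are mapped to genes (arithmetic mean over a gene's
probes per sample) and all datasets are restricted to the genes common to
the distinct platforms. Each dataset then passes a two-stage screen:

1. **Fold filter.** Genes are kept iff the ratio of case-group mean to
   control-group mean is ≤ 0.67 or ≥ 1.5 (boundaries retained). A zero
   control mean gives ratio +inf (kept, with a warning); a gene flat at
   zero in both groups is dropped.
2. **Rank Wilcoxon + FDR.** Expression values are replaced by within-sample
   ranks over the common genes (average-rank ties), each retained gene gets
   a two-sided Wilcoxon rank-sum p (exact enumeration when min(n₁, n₂) ≤ 8
   and the pooled values are tie-free, tie-corrected normal approximation
   otherwise; all-tied input returns p = 1), and Benjamini–Hochberg
   adjustment at FDR 0.10 is applied within the dataset, over the filtered
   genes only. A pooled-FDR mode (one adjustment across datasets) exists
   but is off by default, matching the per-dataset reading.

The final expression-derived gene set is the union of per-dataset
selections. Seeds are assembled with provenance (causative / proteomics /
expression-derived); overlap between sources is allowed and counted once in
the union. All sources enter the activity vector with weight 1 (per-source
weighting is deliberately not fitted).

Note the screen's two stages reuse the same data: genes that pass the fold
filter by chance also tend to have small Wilcoxon p. At the null this keeps
the absolute number of selections very small at realistic sample sizes
(~0.1 genes per 150-gene replicate at 12 vs 12 samples) but the selection
rate is not a calibrated per-gene type-I error — a property inherited from
the screen's design, worth remembering when interpreting real output.

### Enrichment

For a query of n genes from a background of N genes, a term with K members
in the background and overlap k is scored by the hypergeometric upper tail

    p = P(X ≥ k) = 1 − Σ_{i=0}^{k−1} C(K,i) C(N−K, n−i) / C(N,n),

computed in log space (scipy). Terms with zero overlap are omitted by
default. Raw p-values are compared to α = 0.05, with an optional BH mode
(off by default, matching the raw-p convention of this kind of analysis).
The background defaults to the full interactome gene set and is always
recorded in the output (N, K, n, k per record). Query genes outside the
background are clipped with a warning, not an error. Reference-network
overlap is tested the same way with the subnetwork's node set as
background: one test for inner-core over-representation, one for non-seed
over-representation. Tissue-abundance tables use the four-level scale
(negative/weak/moderate/strong); coverage is the fraction of nodes present
in the table, and "detected" means weak or above, as a fraction of all
nodes.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes, with
known ground truth; they make no attempt to mimic real interactome degree
distributions or array chemistry.

- **Network**: module gene pairs connect at density 0.6 with weights
  U(0.6, 1.0); all other pairs at density 0.01 with weights U(0.1, 0.5).
  The weight split mirrors the 0.5 medium-confidence cut so the subnetwork
  floor acts nontrivially; the density contrast makes the module
  recoverable by propagation.
- **Expression**: two platforms; per-gene control level lognormal
  (log-mean 5, log-sd 1); planted genes multiplied by `de_effect` in cases;
  every probe (1–3 per gene) observes its gene's level under multiplicative
  lognormal noise (sd 0.3 on the log scale). Platforms share the module
  genes plus 90 % of the rest; leftover genes split between platforms, so
  the common-gene universe is a strict subset of either platform.
- **Loci**: each held-out gene gets its own chromosome with
  `genes_per_locus − 1` neighbors sampled without replacement from the
  universe, at strictly increasing coordinates, disease gene mid-region.
- **Annotations**: one planted term equal to (a subset of) the module
  genes, the rest uniform draws with sizes uniform on a configurable range.
- **Abundance / reference sets**: a four-level abundance table over 75 % of
  genes; an immune-reference-like gene set containing the whole module plus
  10 % background; a small drug-target-like list half inside the module.

**Reference scenario** (the default `SyntheticScenario`): 2000 genes,
50-gene module, 5 held-out causative genes, 10 + 15 seeds by pseudo-source,
de_effect 2.0, 12 cases vs 12 controls per platform. These sizes are a
deliberate scale-down of a genome-wide study (≈14.5 k genes, ~100-gene
loci, 7 causative genes) that keeps every stage's statistics in the same
regime — locus candidate sets of 100 genes, two-platform harmonization
with ~90 % shared genes, FDR at 0.10 — while remaining fast enough to run
end-to-end in seconds.

Randomness: one integer scenario seed; each generator draws from its own
child stream (`default_rng([seed, stage_tag])`), so any generator is
bit-for-bit reproducible on its own, independent of call order.

### What passing tests do and do not show

The synthetic module is far cleaner than a real disease module: edge
densities are homogeneous, weights are independent of degree, expression
noise is i.i.d. lognormal, and the planted annotation term is exactly the
module. Recovery results (held-out mean r-ratio ≈ 0.02 at φ*, random genes
≈ 0.5) therefore demonstrate correctness of the machinery, not expected
performance on real interactomes, where module boundaries are diffuse and
hub effects bias propagation scores.

## Numerical and design choices

- Ranks are 1-based, descending in s, ties broken by the stable gene order
  of the network — deterministic and permutation-consistent. Candidate-set
  ranks use globally computed scores with within-set rank extraction.
- `r_ratio` drops candidate members absent from the scored network and
  shrinks N accordingly (real locus tables list genes missing from any
  interactome; silently keeping them would deflate every ratio).
- Network readers divide integer-scaled scores (detected by any value > 1)
  by 1000, collapse duplicate undirected edges keeping the maximum, and
  drop self-loops; symmetry and the zero diagonal are constructor
  invariants of `WeightedNetwork`.
- The pipeline writes every stage's output with fixed float formatting and
  no timestamps, so identical (config, seed) reruns are byte-identical.
  A preflight check validates all input paths before any output is
  created; stage failures abort with the stage name, keeping earlier
  outputs.

## Known limitations

- No alternative propagation kernels (random walk with restart, heat
  diffusion); the resolvent form is the point of the package.
- No GO-graph ancestor propagation: terms are flat sets.
- No identifier mapping: gene ids are opaque strings matched exactly.
- The φ grid search is one-dimensional and unweighted across held-out
  genes; with few held-out genes the minimum is shallow and φ* should be
  read together with the written calibration curve.
- Weighted-core (s-core) variants and network visualization are out of
  scope.
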