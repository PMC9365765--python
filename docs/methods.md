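# Methods

## Model and procedure

The analysis treats a tissue as an undirected weighted gene network
with edge weights in (0, 1] (posterior-probability-like functional
interaction scores). A candidate core-gene set is given externally
(e.g. a curated disease-gene catalogue filtered to its stronger
evidence grades). The pipeline runs, per tissue:

1. **Node strength** `s_i = Σ_j w_ij`; core vs peripheral strengths are
   compared with a two-sided Mann–Whitney U test (SciPy: exact null for
   small tie-free groups, tie-corrected normal approximation
   otherwise). "Core-central" additionally requires the core median to
   exceed the peripheral median — the scientific claim is *higher*
   strength, not any difference. Across tissues, the 2×2 table of
   (brain-related × core-central) counts is tested with the uncorrected
   Pearson chi-squared (df = 1) and summarized by the enrichment factor
   (ratio of central proportions).
2. **Community detection**: Louvain modularity maximization at
   resolution 1 on edge weights. Because local-move order is random,
   detection is a seeded best-of-`n_restarts` loop (default 10) keeping
   the highest-modularity partition; identical (network, seed,
   restarts) reproduce the identical partition. Full-network
   communities below `min_size` (default 10) are marked unassigned and
   excluded downstream; core-subgraph clustering uses `min_size` 1.
3. **Concordance**: the core subgraph keeps only edges joining two core
   genes (isolated core genes are dropped and logged). The core and
   full partitions are cross-tabulated; empty rows/columns are dropped
   (the chi-squared expected counts are undefined at zero marginals);
   columns are permuted by maximum-weight assignment
   (`scipy.optimize.linear_sum_assignment`) to place large
   intersections on the diagonal, surplus columns appended by
   descending column sum. Cramér's V = sqrt((X²/n)/min(k−1, r−1)) with
   dimensions counted after the drop.
4. **Sampling control**: subgraphs with as many nodes as the core
   subgraph, drawn without replacement with probability ∝ strength
   (sequential renormalized draws, as implemented by numpy's weighted
   `choice`), clustered and scored against the full partition;
   10 replicates by default, aggregated as mean, sd and a
   t-distribution 95% CI (df = replicates − 1). An edgeless induced
   subgraph is redrawn (≤ 5 retries, logged).
5. **Enrichment**: fixed two-list hypergeometric test, upper tail
   P(X ≥ b) via `scipy.stats.hypergeom.sf`; fold = (b/n)/(B/N); BH
   step-up FDR across all terms tested for one target; significance
   requires p < 0.001 and q < 0.05 (the conventional defaults of
   two-list GO enrichment tools). Unannotated genes count toward N and
   n. Terms are flat sets from a GMT file; no ontology-graph
   propagation. Per cell, the unique union of overlap genes across
   significant terms gives the enriched-gene ratio; −log₁₀ q is used
   for the median significance display. The regrouping null permutes
   gene→cluster labels preserving cluster sizes and re-runs the whole
   per-cluster enrichment.
6. **Phenotype stratification**: subjects carrying a disruptive variant
   in a tested subcluster's genes form the in-group — exclusively, even
   when they also carry variants elsewhere; everyone else is the
   out-group. Welch's unequal-variance two-sided t-test (with
   Welch–Satterthwaite df and a 95% CI of the mean difference, oriented
   out − in) is applied per trait, BH-corrected per trait across cells;
   the family size is configurable because carrier-poor cells may be
   skipped (fewer than 2 carriers).

## Synthetic data

`generate_lfr` produces the weighted planted-community benchmark:
degrees from a truncated power law (exponent 2 by default, lower
cutoff solved so the mean hits the requested average degree, upper
cutoff `max_degree`), community sizes from a truncated power law
(exponent 1.5) on [`min_comm`, `max_comm`]. Each node's expected degree
is split into an internal fraction (1 − μ_w) and an external fraction
μ_w, and edges are realized as independent Bernoulli draws with
degree-corrected (Chung–Lu) probabilities inside each community and
across community pairs; a √-correction keeps expected external degrees
on target despite same-community pairs being excluded. Weights are
i.i.d. Uniform(0.3, 0.7), so the expected external *strength* fraction
per node equals μ_w. Defaults are the full benchmark configuration
(n = 25000, k̄ = 300, k_max = 3000, communities 4000–8000, μ_w = 0.2);
tests and the acceptance script run a 1/10 scale (n = 2500, k̄ = 30,
k_max = 300, communities 400–800, 75-node samples), which preserves
every distributional property the analysis depends on at desk-scale
cost. This construction reproduces the benchmark's *distributions*
(degrees, community sizes, mixing), not the micro-behavior of
stub-rewiring implementations; expected and realized degrees differ by
binomial noise, so low-degree nodes can be isolated (they are excluded
from subgraph clustering, as in any real sparse network).

`generate_tissue` operationalizes the relevant/irrelevant-tissue
contrast: a planted partition backbone (equal-size communities, dense
strong-weight edges within, sparse weak edges between) plus a planted
core set. Each core gene is community-**aligned** with probability
`concordance` — it receives extra strong edges into its own community
(strength boost) and dense strong edges to co-community aligned cores —
and otherwise **scattered**: a couple of weak core–core edges placed
community-blind. At concordance 1 the core subgraph clusters onto the
full communities (V ≈ 1); at 0 its sparse random structure decouples
from them. What the emulator does *not* model: overlapping communities,
degree–community correlations, tissue-to-tissue edge correlation, or
realistic weight distributions — so passing tests demonstrate that the
statistics behave as designed under their own assumptions, not that any
particular biological dataset will show the same effect sizes.

`generate_annotations` builds signal terms (≥ 70–80% of members from
one planted cluster) plus uniform noise terms over the core universe;
`generate_phenotypes` assigns each subject per-gene disruptive variants
(independent Bernoulli, default rate 0.01/gene) and additive
per-subcluster trait effects on Gaussian baselines (IQ 82 ± 15 points,
age of walking 13.8 ± 3 months — cohort-plausible values). Parameter
recovery is tested at n = 3000 subjects, where planted shifts are
estimated within two standard errors.

## Numerical and design choices

* Ties in Louvain local moves are resolved by the backend's seeded
  order; determinism is guaranteed by fixing all seeds and keeping the
  first-encountered best restart. Community ids are canonicalized
  (descending size, ties by smallest member id) so partitions compare
  structurally.
* V is clipped at 1.0 to absorb floating round-up on exactly diagonal
  tables; chi-squared and V agree with independent cell-by-cell
  evaluation to 1e−12 relative.
* Duplicate edges in input files keep the maximum weight ("top edge"
  semantics); self-loops are dropped; out-of-range weights are an error
  by default, clampable by explicit opt-in.
* Degenerate cases raise rather than guess: edgeless networks or core
  subgraphs, all-tied strength comparisons, contingency tables with
  fewer than 2 non-empty rows or columns, zero-variance Welch groups,
  inconsistent hypergeometric counts.
* The per-stage seeds of the study pipeline are CRC32 hashes of
  (master seed, stage, tissue), giving independent, reproducible
  streams below 2³¹.

## Limitations

* Best-of-restarts is a pragmatic stand-in for consolidating
  non-deterministic clustering runs; it does not explore the partition
  landscape exhaustively, and on degenerate near-tie landscapes the
  reported partition depends on the seed.
* Cramér's V rewards any refinement of the column partition: a core
  partition of singletons scores V = 1 against anything. The sampling
  and benchmark controls are therefore essential context for
  interpreting an observed V, and very sparse sampled subgraphs
  (many singleton communities) bias their control V upward.
* The strength-weighted sampling control fixes only the subgraph size
  and the selection distribution; it does not condition on connectivity
  or degree sequence.
* Enrichment treats terms as flat, independent gene sets; correlated
  (nested) terms inflate significant-term counts, which is why
  unique-gene counts accompany them.
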