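# Methods

This note documents the statistical model, the defaults and the numerical
choices behind `gwasnet`, and what the synthetic benchmarks do and do not
demonstrate.

## Model and assumptions

The pipeline treats gene-level GWAS p-values as noisy evidence of
phenotype relevance and a PPI network as a prior on which genes act
together.  Its core assumptions are:

- *Guilt by association*: genes interacting with significantly associated
  genes are themselves more likely to be relevant.  This motivates seeding a
  random walk with restart (RWR) at the nominally significant genes
  (p ≤ 0.05, inclusive) and using the stationary-ish mass `P(T)` as a
  per-gene weight.
- *One-sided evidence aggregation*: per-gene probit scores
  `z_i = Φ⁻¹(1 − p_i)` are combined by the weighted Liptak–Stouffer
  statistic.  The probit of the *survival* probability is used so smaller p
  means larger z; the statistic is exactly the classical Stouffer
  combination when weights are equal (a tested invariant).
- *Empirical standardization*: `Z_A` drifts with set size and with the
  weight distribution, so it is standardized per size k against uniformly
  random gene sets (no connectivity constraint — random *sets*, not random
  subnetworks).  This makes `S_A` comparable across sizes but, importantly,
  it calibrates a statistic of *random* sets, not of *optimized* sets; see
  "Null behavior" below.

The walk runs on the subgraph induced by genes that have a p-value; edge
weights are undefined for unscored genes, and the discarded-node count is
logged.  `P(0)` is deliberately left unnormalized (1 on seeds, 0 elsewhere):
`Z_A` is invariant under uniform rescaling of the weights (asserted to
1e-10 in the tests), so normalizing `P(0)` would change nothing downstream.

## Gene-level test

`Q = Σ_j F⁻¹(1 − p_j)` over the gene's SNPs (1-df chi-square inversion;
SNP p-values clamped to [1e-15, 1]).  The null is simulated from
`MVN(0, Σ)` with Σ the Pearson dosage correlation (mean-imputed missing
dosages, zero-variance SNPs mapped to identity rows, eigenvalues clipped at
1e-8 for positive semidefiniteness).  The empirical p counts simulations
`≥ Q` with no +1 correction, so an exact zero is attainable and is flagged
(`floored`, displayed as `< 1/n_sims`).  The adaptive schedule (10³ always,
10⁴ if p ≤ 0.1, 10⁶ if p ≤ 0.001) concentrates effort on promising genes;
its stage gates are part of the method, not tunables.  Without genotypes Σ
defaults to the identity — an LD-free approximation that is exact for
single-SNP genes and anticonservative for genes in strong LD; supply the
genotype matrix whenever available.

SNP-to-gene assignment is taken verbatim from the user's annotation table;
the package does not impose a gene model or flanking window.

## Synthetic data

Two generators make the pipeline self-contained:

- `gwas_sim` produces LD-blocked dosages by thresholding two independent
  AR(1) latent Gaussian haplotypes per individual at the MAF quantile.
  Marginal genotypes respect Hardy–Weinberg proportions; the realized
  adjacent-dosage correlation is attenuated relative to the latent rho
  (tetrachoric-vs-Pearson gap), which is fine for exercising the LD-aware
  test.  Phenotypes follow `y = Σ β·dosage + covariates + N(0, σ²)` with an
  age-like, a sex-like and a 5-level diagnosis-like covariate; the
  diagnosis factor enters the regression as dummy indicators with the
  reference level dropped, because a full set of level indicators plus an
  intercept is rank-deficient.  Per-SNP QC applies call-rate, minor-allele
  frequency and Hardy–Weinberg (1-df chi-square) filters in that order,
  with defaults 0.95 / 0.05 / 1e-6.  Missing dosages are mean-imputed in
  the regression by default; a complete-case (`drop_missing`) mode exists
  and agrees closely at low missingness.
- `net_sim` produces preferential-attachment (Barabási–Albert) graphs —
  chosen over Erdős–Rényi because the heavy-tailed degree distribution is
  what actually stresses column normalization and the restart walk — with
  `edges_per_node = 2` by default.  The planted signal module is a
  connected subgraph collected by a random walk (a BFS ball would give
  degenerate star shapes); planted genes draw p from U(0, 1e-4) and
  background genes from U(0, 1) by default.

What the generators do *not* emulate: realistic degree-p-value coupling
(hub genes in curated PPI databases are better studied and tend to have
more SNPs and smaller gene-level p-values), LD between genes, gene-length
artifacts of gene-based tests, and inflation of the GWAS p distribution.
Passing benchmarks therefore demonstrates algorithmic correctness and
calibration under clean conditions, not performance on real cohorts.

## Numerical choices

- **Background table smoothing.**  `μ_k` and `σ_k` vary slowly in k, but at
  the desk-scale calibration (200 draws per size) their Monte-Carlo jitter
  is a few percent.  Because the greedy growth rule compares `S` at
  consecutive sizes, that jitter makes `S` non-monotone along otherwise
  clean trajectories and stalls growth almost immediately (top modules of
  5–16 genes against a planted 30-gene module; Jaccard ≤ 0.3).  The search
  therefore applies a centered moving average (window 9, edge-padded) to
  both curves before scoring (`score.smooth_background`;
  `SearchParams.bg_smooth_window`, window 1 disables).  With smoothing the
  planted module is recovered essentially exactly (consensus Jaccard
  0.88–1.0 over replicates).  This is a variance-reduction device, not a
  change of model: it estimates the same `μ_k`, `σ_k` curves.
- **Growth rule.**  Plain hill-climbing with strict improvement in `S`; tie
  between equally scoring candidate neighbors broken by smaller gene p,
  then lexicographic symbol, so runs are exactly reproducible given their
  seed.  Deduplication keeps the first occurrence of identical gene sets;
  ranking is by `S` descending, then smaller size, then sorted gene tuple.
- **Size cap.**  Growth is capped at `min(MaxNetSize, k_max)` since `S` is
  undefined beyond the calibrated range; the desk-scale test profile uses
  `k_max = 60`, 200 draws (the reference profile is `k_max = 500`, 1000
  draws).
- **Degenerate inputs.**  All-zero node weights (e.g. a component farther
  than T steps from every seed) make `Z` undefined: scoring raises, growth
  reports `S = −∞`, and background calibration refuses degenerate draws.
  A run without seed genes returns an empty result with a warning rather
  than raising, so bulk null screens proceed.
- **Clamps.**  p-values are clamped to [1e-15, 1 − 1e-15] before probit,
  [1e-15, 1] before chi-square inversion, and adjusted p to ≥ 1e-300 before
  the log in the combined enrichment score.

## Consensus

Only the top subnetwork of each run seeds a consensus module (the spotlight
is on the most significant finding; matching lower-ranked modules across
runs is ambiguous).  Dice-similarity ties are resolved toward the
better-ranked candidate.  Unique modules are exact-set deduplicates; no
fuzzy merging is applied by default, since near-identical CMs are already
the product of intersections and further merging would blur provenance.

## Null behavior and honest limitations

The `S_A > 3.0` filter reads like a three-sigma rule, but the background
distribution describes *random* gene sets while the greedy search reports
*optimized* ones.  Under a pure-noise simulation (all gene p ~ U(0, 1), so
about 5% of genes are chance seeds whose node weights and z-scores are
correlated by construction), the search still reports at least one module
with `S > 3` in roughly half of runs at the 600-gene desk scale.  Chance
connected clusters of seed genes are exactly what the growth rule is built
to find, and the random-set background cannot price that selection in.
Consequences for practice:

- `S_A` should be read as a ranking score, not as a calibrated z-value;
  module-level significance claims need a dedicated permutation scheme
  (re-running the full search on permuted gene scores), which is outside
  the current scope.
- The consensus stage is the effective false-positive control in this
  design: chance modules differ between runs and shrink or vanish under
  intersection, while planted modules survive it (the recovery benchmark).

Other limitations: Enrichr-style rank z-scores depend on the null-query
ensemble and the background universe, so absolute enrichment z-values are
comparable only within one configuration; the enrichment background
defaults to the working network's genes and should be set explicitly when
the query derives from a different universe; and the gene test does not
replicate any particular annotation pipeline's gene boundaries.
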