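# gwasnet

Network-based pathway analysis for genome-wide association studies (GWAS).

Single-marker GWAS hits rarely tell the whole story: genes with individually
modest association signals often cluster together in protein–protein
interaction (PPI) networks, acting through shared pathways.  `gwasnet`
integrates gene-level GWAS p-values with a PPI network to find such clusters,
and stabilizes the intrinsically stochastic module search by extracting
*consensus modules* across repeated runs.  It is aimed at statistical
geneticists and systems biologists who have SNP- or gene-level association
results and a network, and want reproducible, significance-calibrated gene
modules annotated with pathway enrichment.

## Method

1. **Gene-level testing** (optional, when starting from SNP results).  Each
   gene's statistic is the sum of its SNPs' 1-df chi-square values,
   `Q = Σ_j F⁻¹(1 − p_j)`.  Its null distribution under linkage
   disequilibrium is simulated by drawing `s ~ MVN(0, Σ)` with Σ the SNP
   dosage correlation matrix and taking `Q_sim = ‖s‖²`; the empirical p is
   the tail fraction.  Simulation effort is adaptive: 10³ draws for every
   gene, 10⁴ for genes with p ≤ 0.1, 10⁶ for genes with p ≤ 0.001, and a
   zero count at the final stage is reported as `p < 10⁻⁶`.

2. **Network smoothing.**  Nominally significant genes (p ≤ 0.05) are seeds.
   Edges are weighted by the significance of their endpoints,
   `W_ij = ((1 − p_i) + (1 − p_j)) / 2`, the matrix is column-normalized,
   and seed mass diffuses by a random walk with restart,
   `P(t) = (1 − r)·W·P(t−1) + r·P(0)` with `r = 0.5`, stopped after `T = 5`
   steps.  `P(T)` supplies per-gene node weights.

3. **Subnetwork scoring.**  A gene set A is scored by the weighted
   Liptak–Stouffer statistic `Z_A = Σ_i w_i z_i / sqrt(Σ_i w_i²)` with
   `z_i = Φ⁻¹(1 − p_i)` and `w_i = P(T)_i`, then standardized against random
   gene sets of the same size: `S_A = (Z_A − μ_k) / σ_k`.

4. **Greedy search.**  From every seed gene a module grows by repeatedly
   adding the neighbor that most increases `S_A`, stopping when no addition
   improves it.  Modules with `S_A > 3.0` and size in [5, 300] are kept.

5. **Consensus.**  The search is stochastic (shuffled start order and
   run-specific background calibration), so it is repeated with seeds 1..10.
   The top subnetwork `TN_a` of run *a* is matched to its most similar
   subnetwork in every other run *b* by the Dice coefficient
   `DC(m, n) = 2|m ∩ n| / (|m| + |n|)`, and the consensus module is
   `CM_a = TN_a ∩ (∩_{b≠a} SN_b(TN_a))`.  Identical CMs collapse to unique
   modules; their joint intersection is the *common subnetwork*.

6. **Enrichment.**  Module gene sets are annotated against a GMT pathway
   library: one-sided Fisher exact (hypergeometric) p, Benjamini–Hochberg
   adjustment, a rank-deviation z-score against random queries, and the
   combined score `c = ln(p_adj) · z`.

## Worked example

The package ships a synthetic-data generator so the full pipeline runs
without external data: a scale-free PPI surrogate with a connected 25-gene
module planted in a 400-gene network (p ~ U(0, 10⁻⁴) inside, U(0, 1)
outside).

```python
from gwasnet import *

net = generate_network(400, 2, rng_seed=11)
scores, truth = plant_module(net, PlantSpec(module_size=25, rng_seed=11))
params = SearchParams(bg_k_max=60, bg_n_draws=200, max_size=60)
runs = run_searches(net, scores, params, seeds=[1, 2, 3, 4, 5])
result = run_consensus(runs)
for run in runs:
    top = run.top
    print(f"run {run.rng_seed}: {len(run.subnetworks)} subnetworks, "
          f"top size={top.size} start={top.start} S={top.S:.2f}")
best = max(result.unique, key=lambda cm: cm.S)
print(f"{len(result.unique)} unique consensus modules; "
      f"best: {best.size} genes, S={best.S:.2f}")
print(f"common subnetwork: {len(result.common)} genes")
m = recovery_metrics(best.genes, truth)
print(f"recovery vs planted truth: jaccard={m['jaccard']:.2f} "
      f"precision={m['precision']:.2f} recall={m['recall']:.2f}")
```

Output:

```
run 1: 9 subnetworks, top size=29 start=G0360 S=7.94
run 2: 8 subnetworks, top size=29 start=G0360 S=7.76
run 3: 6 subnetworks, top size=28 start=G0360 S=7.83
run 4: 4 subnetworks, top size=35 start=G0042 S=8.20
run 5: 8 subnetworks, top size=29 start=G0360 S=8.00
2 unique consensus modules; best: 26 genes, S=7.88
common subnetwork: 26 genes
recovery vs planted truth: jaccard=0.96 precision=0.96 recall=1.00
```

Each run finds a top subnetwork of 28–35 genes with adjusted score around 8
(i.e., eight background standard deviations above random gene sets of that
size); the runs disagree on a few peripheral genes, and the consensus
intersection strips them, recovering the planted module almost exactly
(Jaccard 0.96, recall 1.0).

The same analysis is available from the shell:

```sh
gwasnet simulate --n-nodes 400 --module-size 25 --seed 11 --outdir fixture/
gwasnet run-all --network fixture/network.tsv --scores fixture/gene_scores.tsv \
    --seeds 1-5 --bg-k-max 60 --bg-n-draws 200 --max-size 60 --outdir out/
```

which writes per-run module tables, consensus-module node/edge tables, a
match matrix (rank and Dice coefficient of each module's best match in every
other run), SIF files loadable in Cytoscape, and — with `--gmt LIBRARY.gmt` —
enrichment tables.

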