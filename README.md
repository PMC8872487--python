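# grntrend

**Pseudotime-series gene regulatory network trend analysis for
master-regulator discovery in single-cell RNA-seq.**

Trajectory-inference tools assign each cell a pseudotime, but most downstream
analyses test genes one at a time and ignore how *regulatory relationships
between genes* change along the trajectory. `grntrend` targets exactly that
signal. Given a raw UMI count matrix and an externally computed per-cell
pseudotime (from Monocle 3, or any other trajectory tool), it:

1. **Bins cells** into k ordered pseudotime groups (k = 10 by default),
   allowing overlap so every group has at least `min_size` cells, and
   min-max normalizes the group mean pseudotimes to t₁ … t_k ∈ [0, 1].
2. **Builds one directed, weighted GRN per group** by per-gene
   principal-component regression on Pearson-residual-normalized counts:
   each gene in turn is the response, all others are explanatory, the
   response is regressed on the d leading PCs of the explanatory block
   (d ≪ n), and the PC-space coefficients are mapped back to genes. Entry
   (i, j) of the group network W is the coefficient of regulator j on
   response gene i.
3. **Regresses every edge on time**: for each gene pair the k edge weights
   (W_ij¹ … W_ij^k) are regressed on (t₁ … t_k) by simple least squares,
   giving the slope matrix β ∈ ℝ^(p×p). β_ij > 0 means the regulation of
   gene i by gene j strengthens along pseudotime; β_ij < 0 means it weakens.
4. **Ranks genes by the geometry of β**: each gene's profile in β (its row
   and column concatenated) is embedded into 2D with t-SNE, genes are
   k-means clustered, and every gene gets a Mahalanobis distance to the
   embedding centroid. Genes whose regulatory interactions change strongly
   along pseudotime — master-regulator candidates — land in the periphery
   and top the ranking.
5. **Scores gene sets**: each cluster is tested by a one-sided Fisher
   exact / hypergeometric over-representation test, and the full
   Mahalanobis-ranked list by preranked GSEA (weighted running-sum
   enrichment score, gene-label permutation null, Benjamini–Hochberg FDR).

A seeded synthetic-data generator with known latent time and known
time-varying edges makes every stage testable end to end without any
downloads.

## Worked example

Simulate a data set with 50 genes and 2000 cells, where 5 master regulators
drive 10 planted edges whose strengths change linearly in latent time, then
run the whole pipeline from a flat config file:

```bash
grntrend simulate --out data --seed 7 --p 50 --n 2000
cat > run.yaml <<EOF
counts: data/matrix.mtx
pseudotime: data/pseudotime.csv
gmt: data/sets.gmt
out_dir: out
groups.k: 10
groups.min_size: 500
grn.d: 3
embed.perplexity: 10
cluster.k: 10
EOF
grntrend run --config run.yaml --verbose
```

```
[normalized] normalized.csv shape=(50, 1971)
[partition] partition.csv shape=(10, 6)
[grn_01] W_01.csv shape=(50, 50)
...
[beta] beta.csv shape=(50, 50)
[embedding] genes.csv shape=(50, 6)
[ora] ora.csv shape=(30, 8)
[gsea] gsea.csv shape=(3, 7)
wrote 16 stage outputs to out (config hash d1b32f5b4779)
```

29 of the 2000 cells fail quality control (fewer than 1000 UMIs), leaving
1971. The gene table `out/genes.csv`, sorted by Mahalanobis rank, puts
planted-edge genes (`tgt*` targets, `reg*` regulators) at the top:

```
  gene           x           y  cluster    mdist  rank
tgt010 -380.746643  363.491852        9 5.890895     1
tgt008  120.339607 -292.116303       10 4.061761     2
tgt005   10.256155   70.322906        8 1.735028     3
reg004  -19.883177  -74.198441        6 1.680304     4
reg002   55.760395   11.753872        7 1.653690     5
```

Preranked GSEA of that ranking against the shipped gene sets
(`out/gsea.csv`) flags the planted set and not the decoy:

```
       set  size        es       nes  p_value    fdr_q
   planted    15  0.888129  2.202462 0.001057 0.003171
background    35 -0.744526 -3.385812 0.035714 0.053571
     decoy    24  0.332517  0.842413 0.693182 0.693182
```

The planted set (all genes on time-varying edges) is strongly enriched at
the top of the ranking (ES 0.89, p ≈ 0.001); the background (inert) genes
pile up at the bottom (negative ES); the half-and-half decoy is null.
Querying the slope matrix for the regulators of a target gene:

```bash
grntrend regulators --beta out/beta.csv --target tgt005 --top 5
```

```
regulator      beta  sign
   tgt013  0.740131     1
   tgt009 -0.619141    -1
   reg000  0.502108     1
   tgt007 -0.490053    -1
   reg004 -0.446045    -1
```

`tgt005`'s planted driver `reg000` is recovered with the correct
strengthening sign (its planted slope is +1); the co-regulated targets
above it share the same latent programs, which is exactly the network
cross-talk the embedding view is designed to summarize.

## Library use

Every stage is importable; the computational core is exposed as
sklearn-style estimators that compose with pipelines and `get_params`/
`set_params`:

```python
from grntrend import (PearsonResidualNormalizer, PCRegressionGRN,
                      GeneEmbedder, edge_slopes, make_partition)

resid = PearsonResidualNormalizer(theta=100).transform(counts_cells_x_genes)
grn = PCRegressionGRN(n_components=3).fit(resid)   # grn.adjacency_ is p x p
emb = GeneEmbedder(n_clusters=50, random_state=0).fit(beta)
ranked = [genes[i] for i in emb.rank_order_]
```

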