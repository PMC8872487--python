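# Methods

This note documents the model, the estimators, the tunable parameters, the
synthetic-data generator, and the numerical conventions used throughout
`grntrend`, together with the design decisions that were genuinely open.

## Model

Let X ∈ ℕ^(p×n) be a UMI count matrix for p genes in n cells and let each
cell carry a nonnegative pseudotime supplied by an external trajectory
tool. The working assumption is that cells ordered by pseudotime traverse a
biological process during which the *strength* of gene-gene regulation
changes smoothly, and that a gene whose incoming/outgoing regulatory
strengths change strongly is a candidate master regulator of the process.

The pipeline estimates, for every ordered gene pair (i, j), the linear
trend of the regulatory coefficient of j on i across k pseudotime-ordered
groups of cells:

  W_ij^m  (m = 1 … k)  →  β_ij = Σ_m (t_m − t̄)(W_ij^m − W̄_ij) / Σ_m (t_m − t̄)²

with t the min-max-normalized group mean pseudotimes. β_ij > 0 ⇔ the
regulation strengthens along the process. All downstream ranking reads
only β.

## Stages and parameters

### Quality control and gene filtering

Cells with fewer than `qc.min_umi` (default 1000) total UMIs or more than
`qc.max_mito_frac` (default 0.10) mitochondrial reads are excluded; both
bounds are inclusive on the keep side (total = 1000 is kept). Mitochondrial
genes are recognized by the case-insensitive symbol prefix `mt-`
(configurable). Genes detected (count > 0) in fewer than
⌈`genes.min_cell_frac` · n⌉ cells (default 5%) are removed. Filtering runs
once, globally, *before* cells are split into groups and before
normalization, so dead genes never influence the residual means; whether to
filter per group instead was an open choice, and the global variant was
picked for comparability of the gene set across groups.

### Pearson-residual normalization

Counts are variance-stabilized with analytic Pearson residuals under a
negative-binomial null with fixed overdispersion θ (default 100):
μ_gc = (row sum)(column sum)/total, r_gc = (x_gc − μ_gc)/√(μ_gc + μ_gc²/θ),
entries with μ = 0 are set to 0 (they are constants with no regression
information; NaN would poison downstream linear algebra), and residuals are
clipped to ±√n (`norm.clip`, options `sqrt-n`/`none`/value). θ and the clip
rule are the normalization's standard defaults; both are config-exposed.

### Pseudotime binning

Cells are stably sorted by pseudotime (ties keep input order). With
`groups.k` = 10 and `groups.min_size` = 500: if ⌊n/k⌋ ≥ min_size the groups
are disjoint consecutive windows of ⌊n/k⌋ cells with the remainder appended
to the last window (affects ≤ k−1 cells); otherwise k overlapping windows
of width w = min(n, min_size) are placed at starts round(i·(n−w)/(k−1)),
i = 0 … k−1, so the first window starts at the first cell and the last ends
at the last. Even spacing keeps the group times approximately uniform.
Group mean pseudotimes are min-max normalized onto the *closed* interval
[0, 1]: an open interval is unreachable by a continuous min-max map, and
the slope regression is invariant to this choice up to an affine rescaling
of t. If the group means are not strictly increasing (possible only under
extreme overlap), the partition is rejected rather than silently
degenerate.

### Per-group network estimation (PC regression)

Within each group, for each response gene: the explanatory block is all
other genes, transposed to cells × (p−1) and column-centered (no
unit-variance scaling by default — Pearson residuals are already
variance-stabilized; `grn.scale_explanatory` enables it). The block's
singular value decomposition gives the principal components; the centered
response is regressed by OLS on the `grn.d` (default 3) leading component
scores, and the PC-space coefficients are mapped back through the loadings
onto the original genes. The p response fits are assembled into W with a
zero diagonal. When d = p−1 and the block has full column rank this is
exactly ordinary least squares (the acceptance suite verifies agreement to
1e−8); with d ≪ n it is the usual low-rank stabilization. Determinism:
each component is oriented so its largest-magnitude loading is positive,
components with singular values below max(n, p)·eps·s₁ are dropped, and a
zero-variance block yields all-zero coefficients rather than an error.

Each group network is then max-abs normalized (divided by its largest
absolute entry) so edge weights are comparable across groups before the
trend regression — the minimal cross-group calibration; `grn.normalize:
none` disables it for sensitivity analysis, and `grn.sparsify_top_frac`
optionally keeps only the largest-magnitude fraction of off-diagonal
entries (ties broken by row-major position).

### Trend regression

Plain OLS slope per edge, no weighting by group size (groups are
near-equal by construction). Intercepts and per-edge R² are retained as
diagnostics but nothing downstream consumes them. Requires k ≥ 3 and
strictly increasing t.

### Gene embedding, clustering, ranking

Each gene's feature vector is its row and column of β concatenated
(`feature_mode: concat`, length 2p). The row view describes the gene as a
response (incoming regulation trends), the column view as a regulator
(outgoing); regulator queries read rows, while cluster interpretation
concerns the global profile, so the default keeps both. `row` and `col`
modes are available for sensitivity analysis. Features are PCA-reduced to
min(50, 2p, p) dimensions, then embedded in 2D by t-SNE with a fixed seed
(deterministic given the seed). Genes are k-means clustered in the 2D
coordinates (`cluster.k` = 50 by default, n_init = 10, fixed seed) and
labels are renumbered by descending cluster size so they are comparable
across runs. Every gene gets a Mahalanobis distance to the embedding
centroid using the plain sample mean and covariance (denominator p−1) of
all embedded genes — no robust estimator by default, since the centroid of
the full embedding is the intended reference; the ranking is descending
with stable ties. The Mahalanobis distance is deliberately computed in the
2D embedding space, not in the original 2p-dimensional feature space.

### Enrichment

Cluster over-representation uses the one-sided hypergeometric tail
P(overlap ≥ observed) with the universe fixed to all genes that survived
filtering (the population the clusters were drawn from), BH-corrected
across sets within each cluster. Preranked GSEA of the Mahalanobis ranking
uses the weighted running sum: hit increments ∝ |score|^weight (weight 1 by
default; 0 gives the classic Kolmogorov–Smirnov form), miss decrements
1/(N − N_hit), ES = the extremum of the running sum, and a gene-label
permutation null (default 1000 permutations, seeded). The p-value is the
sign-matched tail with add-one smoothing, NES = ES / mean(|permuted ES| of
the same sign), FDR is Benjamini–Hochberg across sets (simpler and
better-defined than the NES-binned estimator), and the leading edge is the
hit genes at or before (after, for negative ES) the extremum. Sets with
fewer than `gsea.min_size` (5) or more than `gsea.max_size` (500) members
present in the ranked list are skipped, as is a set covering the entire
list (the miss decrement is undefined). Gene identifiers match exactly and
case-sensitively everywhere; a config flag enables case-insensitive
matching for gene-set membership (human gene sets are conventionally
upper-case).

### Regulator reports

The regulators of gene g are row g of β — its incoming edges — consistent
with the W orientation above; `--column` flips to outgoing edges. The top-N
report (default 30) orders by |β| with ties broken by gene order, attaches
the k × N matrix of raw per-group edge weights (heatmap input), and labels
each regulator with sign(β): +1 strengthening, −1 weakening. The signed
"regulation model" export emits (response, regulator, sign) for all pairs
within a user-chosen gene list with |β| ≥ threshold (default 0 = all
pairs). These signs describe trends in coefficient strength, not literature
causality; interpretation is left to the user.

## Synthetic data generator

The generator produces what the real-data analyses can never provide:
ground truth. Each cell draws a latent time s ~ Uniform(0, 1). Five master
regulators (default) follow smooth programs r(s) = 1 + c·B(s), where B is a
shared basis of a linear ramp and a quadrature sine pair at two cycles per
unit time, and c is a per-regulator random unit-norm mixture; each planted
edge (response, regulator, a, b) adds (a + b·s)·r(s) to its response's
latent expression, so the regulation strength is exactly linear in time
with sign(b) the ground-truth trend. Defaults: 50 genes, 2000 cells, 10
planted edges with |b| = 1 and baselines keeping the weight in [0.5, 1.5],
latent noise SD 0.1, Poisson counts (gamma-Poisson NB(θ=100) optional) at
2000 expected UMIs per cell with log-normal depth spread 0.3. Remaining
genes are independent noise. Latents are shifted to a strictly positive
floor, converted to per-cell relative abundances, and scaled by depth.

Two generator design points matter and were chosen deliberately:

* **Shared low-dimensional basis.** The per-group estimator regresses on
  d = 3 leading PCs, so the generator's regulator programs span a matching
  low-dimensional space. With mutually orthogonal per-regulator programs
  (latent rank ≫ d) the PC span rotates from window to window and edge
  coefficients collapse unpredictably — a model-misfit failure mode that
  full-rank OLS shares, and precisely what the generator is meant *not* to
  test. The generator exists to validate the implementation of the method
  on data satisfying the method's assumptions.
* **Quadrature sine pair, not a single sine.** Every program must retain
  variance *within every pseudotime window*: where a program is locally
  flat, the measured regulator is locally uninformative and the edge
  coefficient is attenuated by a window-dependent factor, which breaks the
  planted linearity of the trend. A single sine is flat at its extrema and
  a bare linear ramp has uniformly low within-window variance against
  Poisson noise at these depths; the quadrature pair keeps local variance
  high everywhere.

What the generator does **not** emulate: dropout beyond Poisson/NB
sampling, batch effects, branching trajectories, cell-cycle structure,
nonlinear (e.g. switch-like) regulation trends — a logistic-switch option
exists only for robustness experiments. Consequently, passing tests show
the estimator chain is correct and well-calibrated under its own model;
they do not certify performance on real tissues, where pseudotime error
and non-low-rank structure will loosen recovery.

## Validation experiments (what the test suite and acceptance script run)

* PC-regression networks equal the normal-equations OLS matrix at
  d = p−1 on ≤ 20-gene Gaussian fixtures (tolerance 1e−8).
* Edge slopes match the closed-form least-squares solution on ~1000 random
  edges (1e−10) and are affinely equivariant in t (1e−10).
* Planted-edge recovery at the default generator scale over 10 simulation
  seeds: median fraction of recovered slope signs, one-sided Mann–Whitney
  separation of planted-edge genes from background genes in Mahalanobis
  distance, Spearman correlation between estimated and planted slopes, and
  preranked GSEA of the planted set on the Mahalanobis ranking.
* GSEA ES equals a brute-force running-sum enumeration on 10-gene lists
  (exact); permutation p-values are uniform under a random ranking
  (Kolmogorov–Smirnov test, 200 sets × 500 permutations).
* ORA p-values equal exhaustive hypergeometric tail sums on universes
  ≤ 30 (exact).
* Two end-to-end runs with identical config and seeds produce
  byte-identical stage outputs (SHA-256 checksums in the run manifest).

Problem sizes in the suite (e.g. 20-gene/300-cell pipeline fixtures,
300–500-permutation GSEA nulls) are chosen so the whole suite runs in well
under a minute on one CPU while keeping every statistical check at a scale
where its pass/fail criterion is meaningful.

## Numerical conventions and degenerate inputs

* Stable sorts everywhere a ranking or tie appears (cell ordering, gene
  ranking, top-N regulators, sparsification), so outputs are reproducible
  bit-for-bit.
* PCA/SVD sign fixing: largest-|loading| coordinate positive per component;
  ties between equal singular values are left to input order.
* μ = 0 residuals → 0; zero-variance explanatory blocks → zero
  coefficients; constant edges → slope 0 and R² 0; an all-zero β embeds and
  clusters without crashing (all features identical).
* Degenerate geometry (singular 2×2 embedding covariance) and degenerate
  time (zero-variance group means) raise typed errors rather than produce
  NaNs.
* Config-level guards: k ≥ 3 is required for a slope with residual degrees
  of freedom; heavy window overlap (> 80% shared cells between consecutive
  groups) is warned about before running.

## Known limitations

* Pseudotime is trusted as given; no uncertainty in cell ordering is
  propagated.
* One lineage path at a time: branching trajectories must be split by the
  user before analysis.
* No significance test on individual slopes — genes are ranked by
  magnitude and embedding geometry, not per-edge p-values.
* Full-scale runs (≈ 6000–10000 genes) make the per-group SVD loop the
  dominant cost; the per-stage on-disk artifacts let the network stage be
  cached and reused across downstream re-analyses.
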