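# Methods

`dropstab` measures two distinct properties of single-cell RNA-seq
clustering pipelines as technical corruption grows: **cluster quality**
(do clusters respect the global cell-type labels?) and **cluster
stability** (do cell *pairs* stay together across clusterings?). The two
can diverge sharply — clusters may remain pure by type while the
sub-type neighborhood structure inside them dissolves — and the package
exists to quantify that divergence on data whose ground truth is known.

## Synthetic baseline data

Stability analysis needs true cell–cell relationships, which real data
cannot provide, so baselines are simulated. The generator is a
hierarchical gamma–negative-binomial model with cell-type structure
propagated along a divergence tree:

- per-gene baseline means `mu_g ~ Gamma(shape, rate)` — defaults
  shape = 3, rate = 0.3 (mean 10 counts/gene before library scaling);
- per-gene log-fold effects accumulated edge by edge down the cell-type
  tree, each edge adding `Normal(0, sqrt(branch_weight ·
  type_effect_scale))`, so leaves diverge in proportion to tree distance;
- per-cell library factors `L_i ~ LogNormal(0, 0.25)` modeling depth
  variation;
- counts `x_ig ~ NB(mean m = L_i · mu_g · exp(effect), var = m + 0.2 m²)`.

Two tree presets define the study designs. `separate3` is a star of 3
equally distant types (branch weight 1.0): well-separated global classes
with no sub-structure beyond cell heterogeneity. `nested8` nests 8 cell
states in groups of (3, 3, 2) under 3 type nodes; between-group branches
have weight 1.0 and within-group branches 0.02. The within-group weight
was calibrated on generator fidelity: with 2,000 genes, states at weight
0.1 are as separable as full types and nothing can destabilize them,
whereas at 0.02 the default pipeline recovers all 8 states perfectly on
*uncorrupted* data (ARI vs truth = 1.0) while they remain subtle enough
to behave like genuine cell states — sub-populations near the detection
margin. Cell fractions default to uniform across leaves.

Gene-mean and dispersion defaults were chosen so the uncorrupted matrix
has a zero fraction below 0.1, i.e. below the smallest level of the
standard sparsity grid `f ∈ {0.1, …, 0.9}`; every grid level is then
reachable by adding dropouts. Default problem sizes follow the two
design conventions: low-sample datasets (500–1,000 cells) pair naturally
with many genes, high-sample ones with 2,000 genes; the test suite and
worked examples run at 1,000 cells × 2,000 genes, which preserves the
qualitative regime (cells ≪ genes is not required for any conclusion the
package draws) at desk scale.

What the generator does **not** emulate: kinetic transcription models,
UMI versus read-length chemistry, amplification bias, batch effects,
doublets, or empirically fitted gene-mean distributions. Passing tests
therefore demonstrate the pipeline-behavior claims on data with the
stated structure (distinct vs nested types, overdispersed counts, depth
variation), not on any particular real dataset.

## Corruption operators

All operators act on a stored uncorrupted baseline — never cumulatively
across levels — are seeded, and preserve shape and nonnegativity.

**Expression-weighted dropouts.** Within each class (cell type), nonzero
entries are zeroed by weighted sampling without replacement until the
class's zero fraction reaches the target `f` (count rounded half-up), so
the overall sparsity is calibrated exactly up to per-class rounding.
The sampling weight of an entry with value `x` is `exp(−x / x̄_class)`
with `x̄_class` the class mean of nonzero entries: strictly monotone, so
low expression drops preferentially with a single interpretable scale.
The weight is a pluggable interface (`exp_sq`, `rank_inverse`, or any
callable) so alternative dropout profiles can be swapped in. A class
already sparser than `f` is left unchanged with a warning (zeros cannot
be removed); this is also the defined behavior for real datasets, whose
native sparsity is the baseline. Sampling without replacement uses the
Gumbel top-k construction, which is exact and vectorizes.

**Read-depth dropouts.** Binomial thinning: each count `x` becomes
`Binomial(x, depth_factor)`. Expected totals scale by `depth_factor`;
sparsity rises as depth falls. Defined on integer counts only.

**Noise models.** Each entry is independently corrupted with probability
`p`. Model 1 adds `Normal(0, σ₁)`; σ₁ defaults to 0.1 × the standard
deviation of nonzero entries — deliberately light systematic noise.
Model 2 adds `Normal(mu_g, sigma_g)` of the entry's gene, with moments
taken from the input matrix; the phrase "sampled per gene based on a
Gaussian with mean and standard deviation of the gene" is interpreted as
*additive* noise, which keeps models 1 and 2 structurally parallel.
Models 1–2 take the absolute value afterwards to avoid negative
expression. Model 3 replaces the entry with the value at a uniformly
chosen other position of the same cell — random, expression-agnostic
corruption.

## Clustering arms

The baseline arm is the default single-cell pipeline: per-cell depth
normalization to the median total count, `log1p`, PCA (15 components),
a k-nearest-neighbor graph (30 neighbors, self included, Euclidean), and
Leiden or Louvain community detection at resolution 1.0 with
`random_state = 12345`. Neighbor search is exact (brute-force at desk
scale) rather than approximate: determinism given the seed is worth more
here than fidelity to an approximation artifact. Edges carry UMAP-style
fuzzy connectivity weights in (0, 1] (via `umap-learn`'s fuzzy simplicial
set on the exact kNN), matching the default scanpy neighborhood routine;
an unweighted mode is provided as an auditable fallback. Leiden runs
through `leidenalg`/`igraph`, Louvain through the NetworkX API. PCA uses
sklearn's `auto` solver — exact SVD on small inputs, seeded randomized
SVD at scale — so repeated runs with one seed are identical.

K-Means and Ward agglomerative clustering run on the same PCA embedding.
Their cluster number is estimated by silhouette score over k in 2–50:
for K-Means the rounded mean of per-run argmaxes over 10 seeded runs,
for (deterministic) agglomerative a single pass. Above 5,000 cells the
silhouette uses a seeded 5,000-cell subsample for tractability.

The random-within-type null assigns each cell uniformly to one of `n`
clusters of its own type. By construction its homogeneity is exactly 1
(clusters never mix types) while its within-type assignment carries no
information — the reference for "clusters with correct global structure
but no biological sub-type content". The per-type `n` values are taken
from the cluster counts the baseline pipeline produced across corruption
levels, divided by the number of types and rounded (the mapping from
total to per-type counts is exposed as configuration, since it is a
protocol choice rather than a derived quantity).

## Metrics

All metrics are computed from the classes × clusters contingency table.
Entropies use natural logs (the ratios are base-invariant); empty cells
contribute 0 (`0·log 0 := 0`). Homogeneity is defined as 1 when
`H(C) = 0` and completeness as 1 when `H(K) = 0`. The v-measure is 0
when either component is 0. The adjusted Rand index uses the
permutation-model expectation from the marginals; the doubly degenerate
0/0 case (both partitions trivial) is defined as 1.0 and logged,
matching common toolkit convention. The implementation is validated in
the test suite against an independent O(n²) pair-enumeration and
direct-entropy oracle (to 1e-12) and against `sklearn.metrics`.

## Experiment protocol

Stability is always measured against the partition **B** of the
uncorrupted matrix under the default parameters and seed. The baseline
variability protocol re-runs clustering 100 times with distinct seeds on
the uncorrupted data and scores each against B, separating algorithmic
from data-driven variability. Because normalization, PCA (given its
seed) and exact kNN search are deterministic, only community detection
consumes the per-rerun seed; the fitted graph is therefore reused across
re-runs, which changes nothing in the result and much in the runtime.

Sweeps iterate (corruption kind × level × algorithm × parameter
combination × run), defaulting to 10 runs per combination. Per-run
seeds derive from the master seed and the full grid coordinates by
SHA-256, so a sweep is reproducible and collision-free regardless of
iteration order; corruption seeds exclude the algorithm coordinate so
both algorithms see the identical corrupted matrix. Failing grid cells
are recorded with an error status rather than dropped. Results are tidy
(one row per run), so mean ± SD stability/quality curves are a group-by.

## Known limitations

- The generator's independence of genes given type (no co-expression
  modules) makes PCA structure cleaner than in real data; absolute ARI
  levels should not be read as predictions for any real dataset.
- Noise model 2's additive reading is one of several defensible
  interpretations; it is isolated behind the `GenewiseGaussianNoise`
  class so an alternative can replace it.
- The silhouette subsampling above 5,000 cells trades exactness for
  runtime on large designs.
- Imputation is supported only via `evaluate_external_matrix` (any
  externally imputed matrix goes through the identical cluster→evaluate
  path); no imputation method is bundled.
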