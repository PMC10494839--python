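# Methods

## Problem and model

Enterotypes, read literally, are a claim about geometry: that human gut
community compositions form balanced, stable, distinct clusters in the
relative-abundance simplex.  The alternative is a continuous distribution
concentrated near a low-dimensional nonlinear submanifold, possibly with
regions of higher density that are not separated by gaps.  `enteromap`
operationalizes the distinction as a *gate*: a partition of the data counts
as evidence for clusters only when density-based validity (DBCV), stability
(prediction strength), convex-cluster validity (silhouette, Davies–Bouldin)
and balance all hold simultaneously.  The pipeline's verdict is therefore a
falsifiable statement, and the synthetic generators provide both positive
and negative controls for it.

## Synthetic generators

The generators emulate the geometry of 16S stool surveys, not the sequencing
process (no read counts, chimeras or amplicon bias — the method operates on
relative abundances, so neither does the generator).

- **Clustered** (`generate_clustered`): k cluster centers drawn as isotropic
  Gaussians in logit space scaled by `separation` (default 5.0), per-sample
  logistic-normal perturbations of scale `spread` (default 1.0), softmax
  closure; cluster masses allocated by largest remainder so sizes are exact.
  Defaults n = 1500, p = 50, k = 3 — the positive-control condition used
  throughout the tests: separable but with realistic within-cluster spread.
- **Manifold** (`generate_manifold`): latent coordinates uniform on
  [0,1]^d_true pushed through a fixed random sinusoidal feature map (random
  Fourier features; frequency scale = `curvature` cycles per cube width,
  default 1.0) into p logits, optional Gaussian logit noise, softmax.
  Softmax closure (rather than Dirichlet sampling) is deliberate: it is a
  diffeomorphism onto its image, so the latent manifold — and with it
  d_true — survives exactly into the composition and is a testable property.
- **Gradient** (`generate_gradient`): one latent t ∈ [0,1] trades mass
  linearly between two designated dominant taxa (joint share capped at 0.75,
  within the ~0.8 seen for Bacteroides/Prevotella-dominated samples), with
  the remaining mass spread over background taxa by a mildly noisy softmax
  (sd 0.3).  The result is a density-nonuniform continuum with no gap — the
  desk-scale analogue of the Bacteroides/Prevotella trade-off.
- **Zero inflation** (`add_zero_inflation`): i.i.d. dropout plus re-closure,
  matching the sparsity of real tables; all-zero rows are redrawn.

All randomness flows through one `numpy.random.Generator` per call and the
seed is recorded in `params`, so identical arguments reproduce matrices
bit-for-bit.

What the generators do *not* emulate: compositional count noise
(overdispersion at low depth), taxon–taxon ecological correlation beyond
what the latent map induces, and batch effects within one table.  Passing
tests therefore show that the machinery detects/rejects cluster structure
under controlled geometry, not that any verdict on a particular real survey
is correct.

## Preprocessing

Normalization is total-sum scaling; filtering drops taxa that are nonzero in
fewer than 1% of samples or whose relative-abundance standard deviation is
below 0.001.  Both rules are strict inequalities, so ties at the threshold
are kept, and the standard deviation is computed on the relative scale
(where the 0.001 cut is meaningful).  Both predicates are per-taxon, making
the filter order-stable.  The >70%-dominance rule is a sensitivity variant,
off by default; its default policy removes dominated *samples* (the goal is
robustness to extreme single-species microbiomes), with a zero-and-re-close
per-taxon policy available.  Jensen–Shannon distance is √JSD with natural
log — the metric form; Bray–Curtis and JS require simplex rows.

## PCA and loadings

PCA runs on centered, unscaled relative abundances; scores are not whitened
because downstream clustering depends on the variance geometry.  d_PCA is
the smallest prefix of components whose cumulative explained variance ratio
reaches 0.99.  Per-taxon loadings are the Euclidean norm of the
eigenvalue-scaled principal-vector coordinates over retained components.

## Intrinsic dimension

Levina–Bickel local MLE with Euclidean neighbor distances, pooled over
points by arithmetic mean (the original estimator; the MacKay–Ghahramani
inverse-mean correction is available via `pooling="inverse-mean"`).
Aggregation order: pool per k → median over k ∈ [5, 100] per bootstrap
trial → median over 50 trials → round half-up.  Bootstrap trials resample
points with replacement and then drop duplicate rows before the neighbor
query: a resampled point at distance ~0 from its copy contributes
ln(T_k/T_j) terms of order 30 that collapse the local estimates toward
zero, while the deduplicated resample (≈ 0.632·n unique points) retains the
geometry that actually carries the dimension information.  Exact duplicates
in the *input* are instead jittered at 1e-12 scale (logged) so log-ratios
stay finite.  Known behavior: mild negative bias at higher dimension (the
uniform 5-cube at n = 2000 reads 4), documented and tolerated in the tests.

## Embedding quality

Reconstruction MAE is the median over samples of the L1 norm of the residual
when a sample's original coordinates are predicted from its k = 5 nearest
embedding-space neighbors (inverse-distance weights, exact matches take all
weight, leave-one-out).  The L1 norm (not the per-taxon mean) puts MAE on
the scale of total compositional mass, matching reconstruction errors of a
few to ~30% of a sample's mass on realistic tables.  Q_loc/Q_glob come from
the co-ranking matrix: Q_NX(K) averaged below/above the split K* that
maximizes LCMC(K) = Q_NX(K) − K/(n−1).  Quality scores are recomputed after
the discard step, matching the order of the pipeline.  The denoising discard
drops the worst-reconstructed 2% per iteration, capped at 10% of points,
stopping early when the relative MAE improvement falls under 1%.

Isomap uses the dense eigensolver: scikit-learn's ARPACK path takes an
unseedable random start vector, and the embedding contract requires
bit-identical coordinates for identical seeds.  The autoencoder backend is a
small numpy fully-connected denoising autoencoder (d → h → d_target → h → d,
tanh, Adam, Gaussian input corruption), deterministic given its seed; it is
off by default in the pipeline.

## Clustering

PAM is implemented in-package: BUILD initialization, then best-improvement
SWAP passes with a vectorized O(n²) cost update.  SWAP is a local search, so
the descent is additionally started from 4 seeded random medoid sets and the
best objective wins; ties break to the lowest indices, making the result
deterministic.  Spectral clustering and HDBSCAN delegate to scikit-learn
behind the partition contract (noise label −1); a disconnected kNN affinity
graph is flagged with a warning rather than an error.  In embedding spaces
the metric is Euclidean; distribution-based distances apply only to
original-space representations (they are meaningless after projection).
Degenerate cases (all points identical) yield a single cluster.  The sweep
deduplicates identical label vectors and merges their provenance.  Default
grids: k ∈ 2..9 (PAM, spectral), spectral neighborhood sizes {5, 15, 25,
50} or RBF gamma {1, 5, 10, 15} on precomputed distances, HDBSCAN
min_cluster_size {5, 10, 25, 50} × min_samples {5, 10, 15, 20}.

## Validity

DBCV follows the all-points-core-distance formulation: a(x) =
[Σ_{y≠x}(1/d(x,y))^m / (|C|−1)]^{−1/m} with m the representation dimension;
mutual reachability max(a(x), a(y), d(x,y)); per-cluster MST; sparseness =
largest MST edge between internal nodes (degree ≥ 2; all nodes for 2-point
clusters); separation = smallest mutual reachability between internal nodes
of different clusters; validity weighted by cluster size with noise counted
in n.  A lone cluster has no separation and is assigned validity 0.
Coincident points get core distance 0.  The implementation is verified
against an independent brute-force evaluation (explicit loops, Prim's MST)
to 1e-9.

Prediction strength uses repeated (default 10) random half-splits: both
halves are clustered with the same method and hyperparameters; test points
are classified by the training partition (nearest medoid for PAM, nearest
non-noise training point otherwise); the score is the minimum over test
clusters of the co-assigned pair fraction, with sub-2-point clusters
contributing 1; the mean over repeats is reported.

Entropy is Shannon entropy in nats of the non-noise cluster mass fractions
(a 99/1 split gives 0.056, printed as 0.06 at two decimals; base-2 available
via `base="bit"`).  Silhouette/Davies–Bouldin/Calinski–Harabasz are computed
on non-noise points; all-coincident degenerate input returns silhouette 0 by
the zero-denominator convention.  Calinski–Harabasz is reported but not
gated.

Gate thresholds: DBCV strictly > 0; prediction strength ≥ 0.8; silhouette
≥ 0.5; Davies–Bouldin ≤ 0.6; minimum cluster mass ≥ 5% of non-noise points.
Comparisons at the boundary are inclusive (except DBCV's strict
positivity).  Selection among gate-passing partitions maximizes normalized
entropy H/ln k: raw entropy grows as ln k for balanced partitions, so its
argmax always prefers the most-subdivided passing partition (an embedding
artifact that tears one true cluster into stable islands would beat the true
k); H/ln k expresses "most balanced" independently of k and reduces to the
raw-entropy rule whenever candidates share one k.  Raw-entropy ranking
remains available (`selection="entropy"`).

## Pipeline

Stages run preprocess → PCA → intrinsic dimension → embedding sweeps (with
discard) → clustering sweep → metrics → gate → selection → density analysis,
all seeded from one config seed with fixed offsets; a serialized `RunConfig`
reproduces a run exactly.  Prediction strength is computed lazily by
default: only for partitions whose DBCV is positive and whose masses are
balanced, because a failing partner metric already decides every pair
verdict without it (`ps_policy="all"` forces unconditional computation).
Distance-matrix representations are supported but off by default; on them
Davies–Bouldin (which needs coordinates) is undefined and the convex pair
cannot pass.  Multiple tables are never merged (batch effects masquerade as
clusters); the CLI analyzes inputs separately.

Desk-scale problem sizes used by the examples, tests and the acceptance
script — n = 1500, p = 50, two embedding methods with 2-point grids, k ∈
2..5, 5 PS repeats, 20 bootstrap trials — are the package's default
trade-off between statistical resolution and a laptop-friendly runtime;
every size is a config knob and the published-scale grids are the
`validate_config` defaults.

## Density analysis

2-D/3-D t-SNE/UMAP projections are seeded; LOF-flagged points are removed
only when they amount to < 1% of the data (stray slivers, not structure).
KDE is Gaussian with bandwidth = median distance from every point to its
100 nearest neighbors — a scale set by the data's own spacing; density is
evaluated at the data points, so the 70th-percentile threshold is a point
percentile.  High-density regions are connected components at single-linkage
distance ≤ bandwidth (the least-parameterized delimitation rule); regions
under 1% of points merge into noise.  Top taxa are ranked by mean abundance
pooled over all supra-threshold points, with per-region quartile summaries.

## Known limitations

- The verdict machinery is only as good as the representations swept; a
  cluster structure visible under none of the configured embeddings or
  metrics will be missed.
- DBCV's O(n²) distance and MST work bounds practical partition sweeps to a
  few thousand samples per representation.
- The MLE dimension estimator is biased downward for d ≳ 5 at n = 2000;
  reported integer dimensions in that regime are conservative.
- UMAP/t-SNE can tear a manifold; the gate's stability and balance criteria
  are the guard, not the embeddings themselves.
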