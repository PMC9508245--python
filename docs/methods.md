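# Methods

This note documents the models, estimators and numerical choices in
`connvar`: what each stage assumes, which parameters matter and why their
defaults are what they are, what the synthetic cohorts do and do not
emulate, and where the genuinely open design decisions fell.

## The ISV estimator

The inter-subject variability of a region is the mean cosine distance
between subjects' connectivity profiles (rows of the region × region
matrix) over all subject pairs. Cosine distance is scale-invariant per row,
so a subject-wide rescaling of connectivity (global SNR, tractogram size)
does not move the estimate; it is bounded in [0, 2]; and it is undefined
for an all-zero row, which the estimator treats as missing (NaN) rather
than silently zero — a region disconnected by the streamline threshold
carries no evidence, and a silent zero would bias ISV downward. Missing
entries propagate through mean-ignoring aggregation.

Choices a user should know about:

- **Self-entry exclusion** (default on). The region's own matrix entry is
  removed from both profiles before the distance. The self-connection is
  structurally zero in structural connectomes and undefined in functional
  ones; keeping it would add a shared constant coordinate that shrinks all
  distances toward zero. Exposed as `exclude_self`.
- **ROI-size regression** (default on). Mean ISV correlates with regional
  surface area through profile sparsity; ordinary least squares residuals
  on (intercept, size) remove the linear component. Raw size is used, not
  log size. With a (near-)constant covariate the operation degrades to
  centering.
- **Cluster aggregation** is the unweighted mean of non-missing ROI values
  within each cluster.
- **Bootstrap** (default B = 5000) resamples the P = N(N−1)/2 pair rows of
  the distance matrix with replacement and recomputes ROI-level and then
  cluster-level ISV per replicate. Pair rows are not independent (pairs
  share subjects), so the intervals are descriptive rather than exact;
  subject-level resampling is a straightforward variant but changes P per
  replicate and was not made the default because the pair-row scheme
  matches the estimator's own averaging unit.

## Intersession correction

For two-session functional data the within-subject between-session distance
Dist_ses(m, r) measures how much a subject's connectome moves for
non-biological reasons (motion, SNR, equipment state). The correction
regresses Dist_subj on the pair-mean predictor ½(Dist_ses(m,·) +
Dist_ses(n,·)) and keeps the residuals. Two scopes are implemented: one
pooled OLS over all (pair, ROI) entries (default — the model is a single
scalar slope and intercept) and a per-ROI fit. Residuals may be negative
and are deliberately not clipped: clipping would bias the subsequent mean.
If the predictor has no variance the correction is a warned no-op.

The two sessions are processed symmetrically: pair distances per session,
correction per session against the one session-distance matrix, ISV per
session, then the average of the two sessions' ISV vectors. Swapping
session labels leaves the result unchanged.

## Connectome construction

- **Streamline trimming.** Streamlines connecting one ROI pair are
  resampled to 12 equidistant points by arc length; the distance between
  two resampled streamlines is the smaller of the direct and the flipped
  mean pointwise Euclidean distance (streamline orientation is arbitrary).
  Clustering is sequential in input order: a streamline joins the nearest
  existing centroid within 20 mm, else seeds a new cluster; centroids are
  running means of flip-aligned points; clusters with fewer than 3 members
  are discarded. The procedure is a single pass, so the partition can in
  principle depend on input order; in the regimes it is meant for (a tight
  bundle plus distant outliers, separations well above the threshold) it
  does not.
- **Structural matrices.** Streamline counts below 50 are treated as
  unconnected; rows are then normalized to sum to one, giving connection
  probabilities. Re-normalizing the output is a no-op; all-zero rows stay
  all-zero.
- **Functional thresholding.** Proportional thresholding keeps the
  strongest fraction of off-diagonal connections (default 0.75), with ties
  broken deterministically by (row, column) order. The retained density can
  be chosen by scanning cost-efficiency — global efficiency of the
  binarized graph minus its density — over a density grid; efficiency uses
  unweighted hop counts (the cost/density language implies binary
  topology) and disconnected pairs contribute zero.

## Cross-modal correspondence

Distances are compared at the level of macroscopic clusters shared by the
two atlases. For each pair row, ROI size is regressed out across ROIs; the
residuals are averaged over each cluster's ROIs, giving one length-P vector
per cluster and modality; cluster correspondence is the Spearman
correlation between the two modalities' vectors. Pair entries are
dependent — pairs sharing a subject are correlated — so the permutation
null relabels **subjects**: a permutation π of subject labels remaps entry
(m, n) to (π(m), π(n)) (a Mantel-type scheme). Shuffling pair entries
independently would inflate the type-I error. Family-wise error over the K
clusters is controlled by recording the maximum |ρ| across clusters per
permutation; p-values use the (1 + count)/(1 + B) estimator and are
two-sided by magnitude. Permutations are sampled with replacement from the
permutation group, identity excluded.

## Microstructure PCA

Seven metrics per connection (ICVF, ODI from NODDI; FR from CHARMED; FA,
MD, AD, RD from the tensor model), sampled along streamlines as the median
over points, then the median over streamlines. Each subject's table is
z-scored per metric column (guarding against cross-subject and cross-metric
scale differences); rows are pooled across subjects and connections and the
7 × 7 covariance of the pooled rows is eigendecomposed (covariance of
z-scores, not the re-standardized pooled correlation — they differ slightly
after pooling). Eigenvector sign is arbitrary, so components are anchored:
FR loads positively on PC1 (tissue hindrance/restriction), MD positively on
PC2 (tissue complexity). Per-ROI maps average each retained connection's
group-mean score over the connections incident to the ROI.

## Spatially autocorrelated map comparison

Cortical maps are spatially autocorrelated, so the effective number of
independent samples is far below R and naive permutation p-values are
anti-conservative. The null implemented here preserves each map's value
distribution exactly and its spatial autocorrelation approximately:

1. randomly permute the map;
2. smooth the permutation with an exponential distance kernel at each
   candidate bandwidth δ ∈ {5, 10, 20, 40, 80} mm, truncated to the nearest
   10% of ROIs;
3. fit amplitude α² and white-noise β² by least squares of the smoothed
   map's variogram onto the observed map's variogram, keeping the bandwidth
   with the smallest residual;
4. form α·smoothed + β·(fresh permutation) and rank-remap onto the source
   map's sorted values.

The variogram itself is estimated by Gaussian-kernel smoothing of the
squared pair differences over geodesic distance (25 lags spanning half the
maximum distance, kernel bandwidth 1.5 lag spacings). Hard-binned
variograms were measured to be too noisy at parcel resolution: on a
200-parcel sphere, even surrogate maps drawn from the *true* generating
field miss a hard-binned variogram by about twice the tolerance that
smoothed estimation achieves, so binned estimates would make surrogate
quality unmeasurable rather than the surrogates bad.

The SA-corrected p-value correlates surrogates of map x with the fixed map
y (two-sided, (1 + count)/(1 + B)); the naive p-value uses plain value
permutations at the same B and is reported alongside.

## Group comparisons

Mean ISV differences between ROI groups are tested by shuffling group
labels within the union of the two compared groups (pairwise
exchangeability), 10,000 permutations by default, two-sided p-values,
Bonferroni over the supplied comparisons (three for the core / penumbra /
non-MD design). Swapping the group order negates the statistic and leaves
the p-value unchanged.

## Synthetic cohorts: what they emulate, and what not

All generators are pure functions of their parameters and a seed.

- **Atlas**: R points on a Fibonacci lattice of a 100 mm sphere; K
  contiguous clusters from spherical k-means; log-normal ROI sizes (median
  300 area units). Geodesic distance is exact great-circle distance. Real
  cortical geometry (folding, hemispheric structure, non-spherical
  topology) is not modeled.
- **Structural counts**: expected count C·exp(−d/λ) on a random sparse
  symmetric support; subject m multiplies each entry by exp(s·z) with z
  symmetric standard normal and s the mean of the two row σ's (a symmetric
  combination is required for symmetric matrices; the arithmetic mean keeps
  row-wise log-count variance monotone in σ(r)). Observed counts are
  Poisson. Defaults: density 0.2, λ = 60 mm, C = 2000. The count scale
  matters because the 50-streamline threshold is absolute: real tractograms
  put thousands of streamlines on strong connections, and a small C would
  make the same threshold unrealistically destructive.
- **Functional matrices**: tanh(G + Δ_m + τ_m·E) with a shared group
  pattern G, subject deviations Δ_m scaled by σ(r), and fresh symmetric
  session noise. Subjects differ in noise level (τ_m = τ·u_m, u_m uniform
  on [0.5, 1.5]): between-subject differences in measurement noise are
  precisely what intersession correction exists to remove, and with
  homogeneous noise the session-distance predictor would carry almost no
  between-subject information. The tanh squash yields correlation-like
  entries in (−1, 1) without enforcing positive semidefiniteness, which no
  downstream stage needs. No time series are simulated: the statistics
  consume matrices, and direct construction gives exact control of σ and τ.
- **Cross-modal coupling**: the functional deviations mix the structural
  cohort's deviation field with independent noise, entry-wise weight
  max(κ_i, κ_j) of the two ROIs' cluster couplings — a coupled cluster
  shares its entire rows, symmetrically. The attainable cross-modal
  correlation is bounded by the overlap between the structural support and
  the dense functional matrix (entries absent from the support carry
  shared signal the structural distance never sees), which is why the
  cross-modal Monte-Carlo experiments in the tests use a denser support
  (0.6) and flatter decay (λ = 300 mm) than the generator defaults; with
  those conditions a fully coupled cluster reaches mean ρ ≈ 0.35 at
  N = 28.
- **Microstructure**: two latent factors with loadings matching the
  empirically reported signs, factor SDs (1.25, 1.0) so the two components
  have distinct variance shares (≈ 56% / 36% of pooled variance at noise
  0.2) — nearly equal factor variances would make the eigenvalues
  degenerate and the factor directions unidentifiable.
- **Cortical maps**: Gaussian random fields with covariance exp(−d_geo/ℓ),
  sampled by Cholesky with 1e-8 jitter.

Passing tests on these cohorts show that the estimators recover planted
structure under the generators' assumptions (log-normal/Poisson counts,
additive session noise, exponential autocorrelation). They do not show
robustness to real-data features the generators omit: hemispheric symmetry,
distance-dependent tractography biases, heavy-tailed motion artifacts,
non-stationary spatial autocorrelation, or atlas misregistration.

## Numerical conventions

- All randomness flows from explicit seeds; the pipeline derives one
  deterministic substream per stage from a single root seed, so end-to-end
  runs are bit-reproducible.
- Permutation p-values always use (1 + count)/(1 + B); their lower bound is
  1/(B + 1), never zero.
- Thresholding ties break by (row, column) lexicographic order;
  stable sorts throughout.
- Text outputs print numerics at 12 significant digits so reruns are
  byte-comparable.
- Degenerate inputs fail loudly (zero vectors in cosine distance,
  zero-variance PCA columns, empty groups) or degrade to the documented
  fallback (constant covariate → centering; zero-variance intersession
  predictor → warned no-op).

## Scale of the shipped experiments

The test suite and the acceptance script run the Monte-Carlo experiments at
desk scale, chosen so the whole suite completes in a few minutes on one
CPU: cohorts of N = 20–30 subjects, atlases of 60–220 ROIs, 200–500
permutations/surrogates per test, 100–500 replicates per calibration
estimate. Production-scale defaults (B = 5000 bootstrap, 10,000
permutations, 5000 surrogates) remain the function defaults.

## Known limitations

- The bootstrap treats pair rows as exchangeable; intervals are
  approximate (see above).
- Sequential trimming is order-dependent in adversarial geometries.
- Surrogate maps match the variogram, not the full spatial covariance;
  strongly anisotropic autocorrelation would be matched only on average.
- The cross-modal permutation test assumes subjects are exchangeable under
  the null; structured confounds shared across modalities (e.g. age) would
  need explicit modeling, not relabeling.
- Atlases are synthetic spheres; no support for reading real surface
  geometries or FreeSurfer products.
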