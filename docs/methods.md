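# Methods

This note records the models implemented in `chemography`, the numerical
choices behind them, what the synthetic fixtures do and do not emulate,
and the design decisions taken where the method definitions left room.

## GTM

The model is the standard generative topographic mapping: K latent nodes
x_k on a regular grid in [-1, 1]^2, an RBF network phi with M Gaussian
basis functions on the same rectangle plus a bias, a weight matrix W
mapping phi(x_k) to data space, and an isotropic noise precision beta.
The density is a K-component Gaussian mixture with uniform component
prior 1/K and tied spherical covariance; training is plain EM.

Numerical choices:

- **All densities in log space.** Component log-densities are combined by
  log-sum-exp; responsibilities come from a softmax. This keeps the model
  usable at hundreds of descriptor dimensions, where linear-space Gaussian
  densities underflow immediately.
- **Initialization.** W is solved so the manifold spans the top-2 PCA
  plane of the training data (latent coordinates scaled by the square
  roots of the leading eigenvalues), plus seeded Gaussian noise at 1% of
  the weight scale; beta^-1 starts at the larger of the third PCA
  eigenvalue and half the mean nearest-neighbor spacing of the projected
  nodes, squared. Training is deterministic given the seed (PCG64).
- **M-step.** The normal equations Phi' G Phi W = Phi' R T are solved
  directly. By default there is **no ridge term**: the unpenalized update
  keeps the EM log-likelihood trace exactly non-decreasing, which is a
  stated invariant of the implementation and is asserted per step at 1e-8
  in the tests. A singular or non-finite system falls back to a
  least-squares solve with a warning (the normal equations are always
  consistent, so the fallback still maximizes the expected complete-data
  log-likelihood and monotonicity is preserved). An optional `ridge`
  parameter adds per-compound weight decay (bias row unpenalized —
  this keeps the K=1 model's fitted center exactly at the data centroid);
  we measured that a ridge of 1e-3 produces visible per-step decreases
  (~5e-2) of the plain log-likelihood, which is why it is off by default.
  The per-compound scaling makes the fit invariant to duplicating the
  dataset, an invariant the tests also assert.
- **Degenerate fits.** When K and M are large enough to interpolate the
  data exactly, the noise variance collapses; beta is capped so that the
  mean residual cannot fall below 1e-12 per dimension.
- **RBF width.** Twice the spacing between adjacent RBF centers by
  default (`width_factor=2`), the usual smoothness/flexibility compromise;
  configurable.
- **Convergence.** Relative log-likelihood change below `tol` (default
  1e-5) or `max_iter` (default 100).

Classification fits one GTM per activity class on that class's compounds
(in a shared PCA space when PCA is requested, so the densities are
comparable) and combines the class-conditional densities with priors
N_k/N_tot by Bayes' rule. If every class density underflows to zero for a
probe, the posterior falls back to the priors and the compound is flagged
out-of-density rather than silently classified.

## Supervised GTM

Each supervised iteration labels latent nodes and then moves the
manifold; projection is untouched, so a training compound re-projects to
its training position bit-for-bit (asserted in the tests).

Decisions on points the procedure leaves open:

- **Neighborhood for the threshold adjustment**: 8-connected (Moore)
  neighborhood on the latent grid.
- **The divisor N in P' = P + T/N**: the number of contributing compounds
  (those with r_kn > rr) for that node, making the step a mean signed
  displacement bounded regardless of cluster size; `n_convention="total"`
  switches to the dataset size.
- **Unlabeled nodes** keep their current projection as the RBF target
  (the movement sign rule requires a class).
- **Movement space**: post-PCA model space (the space the manifold lives
  in) — displacement vectors and targets are computed there.
- **Stopping**: fixed `n_iters` (default 20) or earlier when latent
  labels are unchanged and W moves by less than 1e-6. If no node is
  labeled on iteration 1, a warning suggests lowering `thr` or adjusting
  `rho` (the lever for imbalanced data).
- **Two classes only**: the labeling margin rule is defined pairwise; the
  implementation rejects more than two classes explicitly.

On fixtures where the unsupervised map is already perfect (all three
quality statistics at 1.0), the movement step can flip a single neighbor
rank and change a statistic by ~0.003 in either direction; the supervised
>= unsupervised property is therefore asserted on blob fixtures whose
unsupervised map is off the ceiling (3-sigma separation in 10-D, where
supervision improves every statistic by 0.03-0.10). At the ceiling the
comparison measures binning jitter, not method behavior.

## Isomap and s-Isomap

Graph: kNN by Euclidean distance (unsupervised) or the class-aware
dissimilarity (supervised), symmetrized as the union of kNN lists; ties
broken by compound index; the largest connected component is retained and
dropped compounds are reported. Geodesics by Dijkstra (non-negative
weights require alpha <= 1, enforced). Embedding by classical MDS:
eigenpairs of -1/2 H D^2 H, coordinates = eigenvectors scaled by
sqrt(lambda), eigenvector signs fixed by making the largest-magnitude
entry positive. Fewer than d positive eigenvalues is an error naming the
deficiency.

- **beta default**: the mean pairwise Euclidean distance of the training
  set (the customary density scale for this dissimilarity). Because the
  exponent uses d^2/beta, datasets whose distances far exceed 1 can
  overflow the exponential; the auxiliary factor beta1 (default 1)
  replaces beta by beta1*beta, and an automatic guard raises beta1 when
  the mean d^2/beta exceeds 50.
- **Out-of-sample projection**: the k nearest training compounds are
  found under the model's dissimilarity; their (small) dissimilarities
  stand in for geodesics, every other geodesic is the best relaxation
  through those neighbors, and coordinates come from the Nystrom form
  with a 2*sqrt(lambda_k) divisor. This convention is forced by the
  requirement that a training compound fed back through the projector
  reproduce its training embedding (verified to 1e-3 relative on flat
  manifolds, and to machine precision when the point's graph
  neighborhood is recovered exactly); the 2*lambda_k variant remains
  available as `scaling="printed"` for comparison.
- **Unknown labels at projection time**: an external compound has no
  class, so its dissimilarities to the k nearest training compounds use
  the same-class branch — nearby compounds dominate the projection and
  their relative placement depends only weakly on label information.
- **The supervised graph and alpha.** The same-class branch is bounded by
  1 while the cross-class branch is bounded below by 1-alpha. For alpha
  well below 1 every compound's k nearest neighbors are therefore
  same-class whenever the class has k members anywhere in the set: the
  graph splits into one component per class and the largest-component
  rule silently discards a whole class. This is the method working as
  designed on cleanly labeled data, but it makes a two-class quality
  measurement vacuous. The two-class swiss-roll evaluation consequently
  uses alpha = 1.0, the end of the valid range, where both branches agree
  to first order at small distances: the graph stays connected across the
  class boundary, local geometry is preserved, and distant cross-class
  pairs are still repelled exponentially. This is the regime in which the
  parameter's purpose — giving cross-class points "a chance to stay
  close" — actually operates.

## Applicability domain

**Ball.** With the centroid a fixed at the data mean, minimizing the
radius rho subject to sum_j w_j |x_ij - a_j|^p <= rho over simplex
weights is a linear program for *every* p >= 1 (the p-th powers are
constants once a is fixed); it is solved exactly by HiGHS. A
`coverage < 1` option peels the most deviant (1 - coverage) fraction,
scored by a full fit, and re-solves on the survivors; the default
coverage of 1 constrains every compound. Degenerate single-point data
gets radius 0 and uniform weights. A brute-force simplex grid search
serves as the correctness reference in the tests.

**LOF.** Exact implementation of k-distance, tie-enlarged neighborhoods,
reachability distance, local reachability density, and the LOF ratio,
with Euclidean distances. Duplicate points drive the mean reachability to
zero; their lrd is capped at 1e12 and flagged instead of dropping
compounds. k defaults to 10. The implementation agrees with a brute-force
double loop to 1e-10 and with an established library implementation to
1e-8 on random data (both asserted).

**AD curve.** Compounds are removed most-outlying-first; each retained
fraction is re-scored by a caller-supplied evaluator returning balanced
accuracy. Fractions leaving fewer than two compounds in a class are
skipped with a warning.

## Map-quality statistics

- Gamma-score: per-compound same-class fraction among the k nearest map
  neighbors (k default 5 — the definition leaves k free), averaged within
  each class and then across classes. kNN ties break by compound index.
- Distance Consistency: a compound is consistent iff its own class
  centroid is *strictly* nearest; exact ties count as inconsistent
  (conservative). Single-class maps score 1.
- Distribution Consistency: the map bounding box is cut into a 15x15
  grid of equal rectangles (configurable); interval edges are half-open
  with boundary points assigned to the lower-index region; each occupied
  region contributes its Shannon entropy over within-region class
  proportions, weighted by occupancy; Z = n log2(n_classes) normalizes.
  The region entropy is the plain Shannon entropy of the class mix —
  zero for a pure region, log2(n_classes) at an equal mix, the two
  boundary behaviors that pin the definition down. With one class Z is
  zero and DC is defined as 1.
- All three are class-mean-of-means, so minority classes carry equal
  weight — the property that makes the scores informative on the heavily
  imbalanced datasets typical of liability modeling.

## PNN

The activation exp((Z-1)/sigma^2) on a dot product Z is a directional
similarity, maximal at Z = 1; inputs and stored patterns are therefore
unit-normalized (a zero vector is an explicit error). Summation is plain
per-class summation by default; a flag enables class-size normalization
as a prior correction. sigma lives in (0, 1] per the usual tuning range,
swept by the shipped preset grid.

## Evaluation harness

Balanced accuracy (Sens + Spec)/2 from explicit confusion counts, with an
explicit error when a class is absent from the evaluation. External
cross-validation is stratified (per-fold class proportions within one
compound of the global ones, asserted) with a seeded shuffle; the harness
takes a model *factory* so that scaling/PCA are fitted inside each
training fold only. Grid search scores every grid point by mean CV
balanced accuracy; only a strictly better score replaces the incumbent,
so grids listed simple-to-complex break ties toward the smaller model —
the shipped presets (SVM nu 0.01-0.91 and gamma 2^-11..2^3, latent grids
5^2..50^2, RBF grids 2^2..7^2, PCA 20-60, PNN sigma (0,1], s-GTM thr
0-0.2 with rho in {30, 40}) are ordered so.

## Structural alerts

Occurrence fractions are computed over *predicted* classes — an alert
explains what the model keys on, not what the assay says; a diagnostic
flag switches to true labels. A descriptor absent from predicted
inactives but present in actives has an infinite enrichment ratio and is
an alert unless rarity-excluded (logged). The 2.5 ratio cut is one-sided
(active enrichment); the inverse ratio is reported alongside for
completeness. Consensus across classifiers is plain set intersection over
a shared descriptor universe.

## Synthetic data: what it emulates, what it does not

The generators are first-class, seeded (NumPy PCG64 — bit-identical
across platforms), and record their parameters in the dataset metadata.

- `gaussian_classes`: spherical class clusters at a controlled centroid
  separation, with imbalance up to the 17:1 active/inactive regime of
  real acute-toxicity collections; `noise_kind="ball"` gives bounded
  noise so that separation > 2*radius yields *strictly* separable
  classes when a test needs that guarantee.
- `labeled_swiss_roll`: an Archimedean-spiral roll with class bands along
  the unrolled coordinate and the ground-truth (arc length, height)
  returned for recovery checks; adjacent coils are near in 3-D but far
  along the manifold — exactly the structure geodesic embeddings must
  resolve.
- `fragment_matrix`: independent Bernoulli fragment occurrences with
  planted class-enriched fragments (default 0.6 in actives vs 0.05 in
  inactives, n=250 per class — strong enough that the planted alert is
  recovered in every seeded replicate, which the tests assert over 100
  seeds).
- `noisy_fringe`: core clusters plus far-flung planted compounds carrying
  the *wrong* label, so outlier exclusion provably raises balanced
  accuracy over the early part of the AD curve.

What passing on these fixtures does **not** show: real descriptor spaces
are high-dimensional, heavy-tailed, collinear and block-structured
(fragment counts, surface areas, charges mixed); fragment occurrences are
strongly correlated through substructure nesting; class boundaries are
not spherical. Results on the fixtures validate the *mechanics* —
formula correctness, monotonicity, determinism, directional improvements
of supervision, recovery of planted structure — not real-data predictive
performance.

## Parameter defaults at a glance

| Parameter | Default | Meaning |
|---|---|---|
| GTM `K`, `M` | 100, 16 | latent nodes, RBF centers (perfect squares) |
| GTM `width_factor` | 2.0 | RBF width / center spacing |
| GTM `tol`, `max_iter` | 1e-5, 100 | EM stopping |
| GTM `ridge` | 0.0 | optional per-compound weight decay |
| s-GTM `thr`, `rho`, `rr`, `n_iters` | 0.05, 40, 0.01, 20 | labeling threshold, neighbor scale, responsibility radius, iterations |
| Isomap `k`, `alpha`, `beta_s`, `beta1` | 8, 0.3, mean pairwise distance, 1 (guarded) | graph and dissimilarity scales |
| Ball `p`, `coverage` | 2, 1.0 | metric order, constrained fraction |
| LOF `k` | 10 | neighborhood size |
| Gamma `k`; DC grid | 5; 15x15 | map-quality resolution |
| PNN `sigma` | 0.2 | kernel width on the unit sphere |
| Alerts `rarity_cut`, `ratio_cut` | 0.05, 2.5 | rarity and enrichment cuts |

## Known limitations

- Latent space is strictly 2-D; no 3-D maps, no GTM mixtures, no
  missing-data EM.
- s-GTM supervision is two-class only.
- No landmark/sparse Isomap: geodesics are dense all-pairs, O(n^2 log n),
  comfortable to a few thousand compounds.
- Ball assumes the centroid is the natural center; heavy asymmetry calls
  for coverage < 1.
- The structure adapter computes Morgan fingerprints only; it does not
  standardize structures (aromatization/neutralization are upstream
  concerns).
- Problem sizes in the test suite (hundreds of compounds, grids up to
  10x10) were chosen as the smallest at which each property is cleanly
  measurable; all scale knobs are exposed.
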