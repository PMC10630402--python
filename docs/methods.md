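# Methods

This note documents the models implemented in `socialcpm`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical and design choices made where the
procedure was genuinely open.

## Behavioral scoring

A one-back run consists of blocks of 10 images alternating between
attend-faces and attend-houses conditions, with 4 or 5 "same" trials
among the 9 scorable images of each block. Scoring conventions:

- The first image of a block generates no scorable trial (a one-back
  judgment is undefined without a predecessor).
- A missing response is scored like "different": hits and false alarms
  are both defined through responding "same", so a non-response can
  contribute to neither.
- The log-linear correction (add 0.5 to hit and false-alarm counts, 1 to
  both trial totals) is applied *unconditionally*, not only at extreme
  proportions. Conditional application would make d′ non-monotone across
  subjects whose raw counts straddle the correction boundary.
- Φ⁻¹ is the standard normal quantile (scipy's `norm.ppf`); the test
  suite checks it against the independent stdlib `NormalDist.inv_cdf`
  implementation to 1e-10.

The simulated observer is equal-variance Gaussian with an unbiased
criterion d′/2; at ~5,000 scorable trials the scored d′ recovers the
generating sensitivity within ±0.1.

## Connectivity and the edge-index convention

Connectivity is the Fisher transform atanh(r) of the Pearson correlation
between node timecourses. ("z-scored correlation" is read as the Fisher
r-to-z transform, the standard connectomics normalization; standardizing
r across edges instead would make an absolute selection threshold such as
|r| > 0.2 incoherent.) The diagonal is never written or consumed
(atanh(1) is infinite), and an off-diagonal |r| = 1 is treated as a
degenerate duplicate signal and rejected.

Edge vectors are the row-major strict upper triangle: edge k ↔ pair
(i, j), i < j, ordered (0,1), (0,2), …; 0-based internally, 1-based node
ids in the `n{i}_n{j}` CSV headers. All modules share this map; for 268
nodes it yields 35,778 edges. Vectorize/devectorize are exact inverses
off-diagonal.

## CPM

Per training fold: (1) residualize the target on the confounds by OLS
with intercept, coefficients estimated on training subjects only and
applied to compute the held-out subjects' residualized targets (this
avoids leakage while keeping the residualization inside the fold);
(2) select edges by Pearson correlation with the residualized target,
strict |r| > threshold (a tie at the threshold is excluded), split into
positive/negative tails by sign; (3) sum each subject's selected edges
into tail strengths; (4) fit a linear strength model and predict the
held-out fold. Accuracy is the Spearman correlation (average ranks for
ties) between observed residualized and predicted scores over all
subjects.

Defaults: threshold 0.2, k = 10 folds, 100 fold shuffles, 1000
permutations, robustness fraction 0.97.

Open choices resolved as follows:

- **Model mode.** Default `combined`: one OLS with positive and negative
  strengths as two predictors, producing the single predicted score per
  subject that a single accuracy stream requires. `separate_tails` (one
  model and one accuracy per tail) is provided as an alternative since
  the protocol wording is ambiguous; single-tail modes exist for masked
  second-stage runs.
- **Degenerate tails.** A tail that selects no edges contributes a
  constant-zero strength column; the OLS falls back to the minimum-norm
  least-squares solution, which drops that predictor, keeping the
  pipeline total. Zero-variance edges are unselectable and logged.
- **Fold assignment.** Seeded uniform shuffle, then contiguous chunking
  into folds whose sizes differ by at most one (67 subjects → folds of 6
  or 7). Iteration i uses seed + i, so runs are exactly reproducible.
- **Selection frequencies** are tracked per tail (mean over folds, then
  over iterations). The robust mask thresholds each tail separately; an
  edge reaching the fraction in both tails is kept in its more frequent
  tail.
- **Permutation test.** Each randomization permutes the behavior rows
  *jointly with their confound rows* against the connectomes — only the
  brain–behavior link is broken; the behavior–confound relation is a
  property of the behavioral variable. p = (1 + #{null ≥ observed
  median}) / (n_perm + 1) by default, which is a valid test with p > 0;
  the plain count/n convention is available via `counting="paper"`. For
  speed the permutations are vectorized within one seeded fold split;
  under the null the accuracy distribution is invariant to the split, so
  this changes nothing distributionally (verified empirically: on null
  data the fraction of p < 0.05 is ~0.04–0.05 and the p-values pass a KS
  uniformity test). `independent_splits=True` re-splits per permutation.
- **Masked mode.** A feature mask restricts the *candidate* edges;
  selection still re-correlates and re-splits them into tails against
  the new target, and predictions provably use no edge outside the mask
  (zeroing all out-of-mask edges leaves predictions unchanged — tested).

## Bootstrap EGA

Item associations are plain Pearson correlations with pairwise deletion
(each entry uses the participants observed on both items; every pair
must share ≥ 3). Pearson matches the multivariate-normal parametric
bootstrap; polychoric correlations would be the natural extension for
coarse ordinal scales and are deliberately out of scope. If deletion
leaves the matrix indefinite, the nearest-PSD repair (eigenvalue
clipping, rescaled to unit diagonal) is applied and logged.

The network is a graphical-lasso partial-correlation matrix with the
penalty chosen by extended BIC (γ = 0.5). The penalty path descends
logarithmically from the largest absolute off-diagonal correlation to
0.05× it over 30 points, stopping early once EBIC has not improved for 4
consecutive penalties; the solver tolerance is 5e-3. These are
deliberately economical settings: EBIC is quasi-convex along the path
and the dense small-penalty fits dominate runtime inside the bootstrap,
while community recovery on data with realistic structure is unchanged
versus a long high-precision path (checked on pilot data: identical
Louvain partitions, ARI 1.0). All of n_alphas, min_ratio, γ and the
tolerance are configurable.

Louvain community detection runs on absolute edge weights (modularity is
defined for nonnegative weights; signs remain in the network itself) and
is seeded, hence deterministic. Bootstrap replicates are multivariate
normal draws of the original sample size from the estimated correlation
matrix; the typical network is the entrywise median of replicate
networks; final membership is Louvain on the typical network. Replicate
partitions are aligned to the final one by maximum-overlap Hungarian
matching; replicate communities with no match contribute to a reported
"unmatched" mass, so item-stability rows sum to 1 minus that mass.

Network scores weight each member item by its within-community strength
(sum of absolute typical-network weights to other members), normalized
to sum to 1 — the published EGA scoring approach; uniform weighting is
available. Missing responses are mean-imputed within item (logged); a
participant missing every item of a community scores NaN. Scores are
standardized to mean 0, sd 1 over scored participants. A scree of the
correlation-matrix eigenvalues is provided as a dimensionality
diagnostic only.

The comparison run with the Walktrap algorithm reported alongside the
original Louvain analysis is noted here but not implemented.

## Synthetic-data generators

The generators define the conditions under which the pipeline is tested;
they are first-class, tested code.

- **Planted-edge connectomes.** Behavior is standard normal; each signal
  edge is effect·behavior + √(1−effect²)·noise (unit variance, so the
  population edge–behavior correlation *is* the effect size), other
  edges are independent noise, and a motion-like confound correlates
  with behavior at a configurable level (default −0.30, matching the
  observed motion–performance association in the study design this
  emulates). Signal is planted directly on Fisher-z edge values rather
  than via latent node timecourses because CPM consumes edge vectors and
  direct planting gives exact per-edge ground truth; a latent-timecourse
  generator exists for connectivity-stage integration tests. Defaults
  (67 subjects, 268 nodes) mirror the imaging-study dimensions; tests
  use smaller node counts to keep runtimes in seconds.
- **Trait scores.** Three traits load on one common factor with loading
  0.894 (pairwise correlations ≈ 0.8, as strongly correlated trait
  communities show in practice); the first trait additionally loads on
  the behavior with 0.22 placed in its unique variance. The value 0.22
  was fixed by a design (power) analysis: it gives the sharing trait a
  unique (partial) behavior correlation ≈ 0.4, large enough for reliable
  second-stage detection, while its *marginal* correlation with behavior
  stays small (≈ 0.22), consistent with the near-zero trait–performance
  correlations typical of such data.
- **Questionnaire items.** Latents are multivariate normal with the
  specified community correlations (default: 3 communities, r = 0.5 —
  the communities are deliberately non-orthogonal); items are loadings ×
  latents + unique noise with unit marginal variance, discretized by
  equal-probability normal thresholds into 4 categories, then thinned
  completely at random (default 10%). Equal-probability thresholds and
  MCAR missingness are conventional simplifications: real instruments
  have skewed category usage and structured missingness, which these
  generators do not emulate. Passing tests therefore demonstrate
  correctness of the *procedure* under its own generative assumptions,
  not robustness to real-data pathologies.

All generators are bit-reproducible given their seed.

## A known limitation: covariate-induced collider associations

In the second-stage analysis, each trait is predicted from the
first-stage robust network with the other two traits as covariates. When
the traits share a common factor and one trait additionally carries the
brain-related behavior in its unique variance, residualizing a
*non*-sharing trait on the sharing trait conditions on a collider: the
regression transfers a small negative copy of the behavior component
into the non-sharing trait's residuals, creating a genuine (suppressor)
conditional association between those residuals and the planted edges.
The permutation test, correctly, sometimes detects it: in simulations at
the default settings the non-sharing traits reach p < 0.05 in roughly
15–25% of datasets rather than the nominal 5%, and this excess cannot be
removed by tuning the sharing trait's loading without also destroying
the power to detect the sharing trait (verified by a scan over the
loading). This is a property of the covariate design itself, not of the
implementation; interpreting second-stage specificity on real data
should keep it in mind.

## Problem sizes used in tests

The acceptance-style tests run at reduced but statistically meaningful
sizes chosen as part of the package design: null calibration at 60
subjects × 40 nodes with 200 permutations × 100 replicates;
planted-signal recovery at 100 subjects × 50 nodes × 30 edges (effect
0.55) over 20 seeds; bootstrap EGA at 1000 participants × 48 items with
100 replicates over 10 seeds. The defaults in the code (10 folds, 100
iterations, 1000 permutations, 500 bootstrap replicates) remain the
full-protocol values.
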