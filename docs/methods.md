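# Methods

This note records the models, algorithmic choices and study conditions behind
`skelfuse`, at the level of detail a maintainer or reviewer needs to judge
what the package computes and what its tests do and do not demonstrate.

## Data model

All analysis is restricted to a binary 3-D *skeleton* mask of M voxels. The
voxel↔vector bijection is fixed as row-major (C) order over the grid,
0-based; every stage works on `(n_subjects, M)` matrices and maps back to
NIfTI volumes through that bijection. Affines are carried through untouched;
no world-space geometry is interpreted. Missing values in loaded volumes are
imputed at load time with the voxel's across-subject mean for that metric
(count logged) — this preserves voxel-wise group means in expectation and is
a declared choice, since how missing values arise is upstream of this
package.

## Synthetic cohorts

The generator emulates, at the derived-metric level, a two-cohort
skeletonized diffusion-MRI study. Defaults are the study conditions used
throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_a`, `n_b` | 46, 23 | preterm-like (A) and term-like (B) group sizes |
| `grid_shape`, `skeleton_fraction` | 28³, 0.08 | grid and mask density (M ≈ 1800) |
| `effect_sizes` | d ∈ 0.8–1.2 on dti_fa, mk, ak, icvf, forecast_fa | Cohen's d of the planted focal decrease in group A |
| `n_clusters`, `cluster_radius` | 3, 2.5 voxels | planted-cluster layout (per-metric cluster counts allowed) |
| `latent_views` | d_perp, isovf | metrics loaded by the shared latent component |
| `latent_effect` | 1.5 SD | group separation of the latent subject scores |
| `latent_amplitude` | 1.0 × noise SD | peak spatial loading of the latent |
| `spatial_smoothness` | 2.0 voxels FWHM | Gaussian autocorrelation of subject noise |
| `noise_sd` | 0.1 | per-voxel noise SD (baseline is a smooth field ≈ 0.5) |

Construction per metric: smooth positive baseline + planted shift
(−d · noise_sd in group A at cluster voxels) + latent term
(smooth non-negative loading × per-subject score, shared across latent views
up to a per-view scale) + spatially smoothed Gaussian noise rescaled to
`noise_sd`. The skeleton is a union of random smooth 3-D walks — curvilinear
geometry exercises connected-component code paths far better than solid
blocks. Generation is a pure function of the seed (bit-identical replay).

What the generator does *not* emulate: registration/projection artifacts,
metric-specific value ranges and bounded supports, cross-metric noise
correlation beyond the latent term, covariates (age at scan, sex), and
scanner/site effects. Passing tests therefore demonstrate correctness and
calibration of the *procedures* under a controlled generative model, not
performance claims on real neonatal data.

## Voxel-wise inference

- Pooled-variance two-sample t per voxel, signed for a one-sided contrast
  (`A<B` or `B<A`); both directions can be run separately. Zero-variance
  voxels score t = 0 with a warning rather than ±∞ (synthetic edge case).
- TFCE with E = 1, H = 2, 26-connectivity, Δh = 1/100 of the map maximum —
  the convention established for skeletonized data. The integral is
  discretized at heights i·Δh, i = 1..⌊1/dh⌋; negative statistic values
  contribute nothing. The implementation processes thresholds in descending
  order with an incremental union-find over a precomputed neighbour table
  (numba-compiled); this is algebraically identical to labelling components
  at every threshold (the test suite checks equality against a brute-force
  flood-fill oracle to 1e-10) and roughly 30× faster, which is what makes
  500-permutation runs on hundreds of cohorts practical.
- FWE correction by the permutation distribution of the maximum TFCE
  statistic under subject-level relabelling preserving group sizes. The
  Monte-Carlo estimator is (1+b)/(1+B), valid by construction; exhaustive
  enumeration (including the identity relabelling, p = b/B) is used when
  C(N, n_A) is below a cap. The correction is rank-based, hence invariant to
  monotone transforms of the enhanced map.
- Cluster report: connected components of {p_FWE < α} with size, peak value,
  peak location (ties → smallest row-major index) and minimum corrected p.
  The reported *peak value* is 1 − min p_FWE within the cluster: in the
  source material's cluster table every printed peak equals one minus the
  corrected p even though its caption calls it the highest t — the table
  format follows the printed numbers, not the caption.

## Classification

- Phase 1: stratified 5-fold outer CV; per fold min–max scaling to [0,1] fit
  on the learning set only (test values clipped); inner stratified 5-fold
  grid search over C × kernel × feature-fraction maximizing mean validation
  F1 (group A positive). The inner fold count is not dictated by the design
  source; 5 is chosen for symmetry with the outer loop. Univariate selection
  scores features by the two-sample F statistic (equivalent to t² here),
  computed on inner training data only.
- Tie-breaking: grid candidates are ordered kernel-block first (linear, RBF,
  polynomial), then feature fraction, then ascending C, and the first
  maximizer wins — so exact inner-CV ties resolve toward the simpler kernel
  and smaller C, consistent with the consensus rule (modal C and kernel
  across folds; ties → smaller C, simpler kernel; feature fraction fixed at
  100% since selection proves not beneficial on this design).
- Phase 2 re-runs the outer CV with the consensus hyperparameters and no
  inner search, keeping the metric comparison controlled.
- Weight maps: per-fold linear-SVM coefficients mapped back through the
  selector (zeros at unselected voxels), averaged across folds, rectified,
  min–max normalized to [0,1]. Rectification before normalization matches
  the relevance-ranking interpretation (and the uniformly negative
  weight-vs-p correlations). When phase-1 folds disagree on the kernel, the
  weight map is extracted from the consensus (linear) classifier re-run in
  the outer CV — the map belongs to the *selected* estimator, not to
  whichever kernel an individual fold tried.

## Concordance

The "normalized significance map" is the FWE-corrected p-vector itself
(already in [0,1]); the weight map is the normalized |w| above. Reported per
metric: sample Pearson r with its two-sided p, and the first-order 1-D
Wasserstein distance computed as the mean absolute difference of matched
order statistics (equal voxel counts by construction; equals the integral of
the absolute quantile-function difference). Where a true effect exists, low p
co-locates with high weight, so r < 0; across a battery of metrics with
varying effect size *and extent*, larger |r| accompanies smaller distance.

## Multi-view CCA

- Objective: SUMCOR — maximize the summed pairwise correlations of the
  per-view variates under the regularized unit-variance constraint
  W_kᵀ(C_kk + cI)W_k = I; solved as a generalized eigenproblem on the block
  cross-covariance matrix (off-diagonal blocks C_ij, zero diagonal) against
  the block-diagonal regularized autocovariance. The solve is reduced to each
  view's row space by SVD — exact for the linear kernel, and the reason the
  eigenproblem stays ≤ n_views·N dimensional however many voxels a view has.
  At c = 0 with more features than subjects the autocovariance is singular
  and the fit refuses with advice to set c > 0.
- Sign convention: view 1's leading weight is made positive; every other
  view's variate is flipped to correlate non-negatively with view 1's,
  component-wise. CCA is sign-invariant; the convention only makes reports
  reproducible.
- Hyperparameters: subject-level 5-fold CV over 10 log-spaced c in
  [1e-4, 1e2] × D ∈ 1..5, scoring the mean held-out between-view correlation
  over folds, components and view pairs; ties prefer smaller D, then larger
  c. Held-out correlation is the declared surrogate for held-out prediction
  error.
- Group screening: per (component, view), outliers outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (fences pooled over both groups) are removed,
  then a two-sided Mann–Whitney U test (exact null when the smaller group has
  ≤ 8 subjects and no ties; tie-corrected normal approximation otherwise),
  then Benjamini–Hochberg across the full component × view family.
  Components significant in ≥ 2 views are *joint*, in exactly one *unique*.
- Spatial maps: structure coefficients (feature-variate correlations),
  z-scored across features per view.

### What in-sample variates can and cannot show

A caveat the test design respects: with N subjects and a view of effective
rank r, the fitted in-sample variate of a view carrying *no* signal still
acquires correlation ρ with any cross-view consensus direction, with
ρ² ≈ r/(r+N) — at any regularization, because the view's Gram matrix can
partially represent every subject-space direction. Consequently, when some
views share a group-separating latent, in-sample variates of pure-noise views
inherit part of the group contrast, and a per-view significance screen on
fitted variates cannot be expected to be *exactly* specific to the loaded
views. The suite therefore checks specificity of the screening operator on
components with planted variate structure, and checks the fitted pipeline
end-to-end for what it can deliver: model-order recovery (D* = 1 for a 1-D
planted latent), joint labelling that includes the loaded views, and a high
canonical correlation for the planted pair. Claims of exact view-level
specificity on fitted models would require held-out variate scores, which is
outside this design.

## Study conditions used by the heavy tests

Chosen once, on generative-realism grounds, and fixed:

- FWE calibration: 200 independent null cohorts, N = 20 (10 vs 10), M ≈ 500
  (14³ grid, fraction 0.183), smoothed noise, 500 permutations each;
  family-wise positive rate compared with the binomial 95% band around 0.05.
- Classifier recovery: N = 69 (46 vs 23), M ≈ 2000 (30³ grid, fraction
  0.075), d = 3 planted at ≈ 50 voxels (5 clusters, radius 2.5); null runs
  permute labels of the same cohort, 10 seeds.
- Concordance battery: 6 metrics with effect size 0.8→3.0 and extent 1→12
  clusters on M ≈ 800; 300 permutations per metric.
- Fusion: 4 views on M ≈ 270 (14³ grid, fraction 0.1), 1-D latent in views
  1–2 with amplitude 2 × noise SD and 2 SD group separation; 20 seeds for
  selection, 25 for the screening-specificity check.
- `scripts/acceptance.py` uses the same conditions at further reduced counts
  (50 null cohorts, 3 null classifications) to stay within a couple of
  minutes.

## Numerical notes and limitations

- TFCE threshold grids are map-relative (Δh = dh·max); comparing enhanced
  values across maps with very different maxima therefore compares slightly
  different discretizations — irrelevant for the rank-based permutation p.
- The Monte-Carlo p floor is 1/(B+1); exhaustive p's floor is 1/B.
- Min–max scaling can map degenerate (constant) learning-set features to 0;
  the selector's F statistic warns and such features carry no weight.
- Eigen-solves use symmetric `scipy.linalg.eigh`; determinism holds to
  floating-point reproducibility on a fixed platform, which is what the
  determinism tests assert (bit-identical re-runs in the same environment).
- No covariates, variance smoothing, nonlinear CCA kernels, sparse penalties
  or cluster-extent thresholding: all deliberately out of scope.
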