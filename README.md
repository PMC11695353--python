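# skelfuse

Skeleton-restricted voxel-wise inference, maximum-margin prediction and
multi-view CCA fusion for multi-metric diffusion MRI.

## The problem

Studies of white-matter development — prototypically preterm-born neonates
scanned at term-equivalent age against term-born controls — derive many
scalar microstructural metrics per subject (DTI-FA, diffusion-kurtosis MK/AK/
RK/KFA, NODDI ICVF/ODI/ISOVF, FORECAST diffusivities, multi-tissue CSD
amplitudes) and project them onto a common white-matter *skeleton*, a thinned
binary mask of tract centres. Three complementary questions then arise:

1. **Inference** — *where* do the groups differ? Voxel-wise two-sample tests
   with family-wise error control over thousands of correlated voxels.
2. **Prediction** — can a single subject's map classify group membership, and
   *which voxels carry the discriminative weight*?
3. **Fusion** — do the many metrics share latent structure, and is that
   structure group-discriminative *jointly* across metrics or *uniquely* in
   one?

`skelfuse` implements this three-level analysis as a tested, reusable
pipeline, together with a synthetic-cohort generator that plants known
effects so every stage has a recoverable ground truth.

## Methods at the core

**Voxel-wise inference.** Per voxel $v$ the pooled-variance two-sample
statistic $t(v)$ is enhanced by Threshold-Free Cluster Enhancement,

$$\mathrm{TFCE}(v) = \sum_{0 < h \le t(v)} e_h(v)^{E}\, h^{H}\, \Delta h ,$$

where $e_h(v)$ is the size of the connected suprathreshold component
containing $v$ at height $h$ (defaults $E=1$, $H=2$, 26-connectivity,
$\Delta h$ = 1/100 of the map maximum). Family-wise error is controlled by
the permutation distribution of $\max_v \mathrm{TFCE}(v)$ under subject-level
relabelling: $p_{\mathrm{FWE}}(v) = (1 + \#\{\max^{(b)} \ge
\mathrm{TFCE}(v)\})/(1 + B)$, or the exact $b/B$ over all distinct
relabellings when enumerable.

**Prediction.** A two-phase support-vector design: phase 1 runs stratified
5×5 nested cross-validation on one anchor metric over the grid
$C \in \{10^{-3},10^{-2},10^{-1},1,10,10^{2},10^{6}\}$,
kernel ∈ {linear, RBF, polynomial degree 3}, univariate feature fraction ∈
{20, 40, 60, 80, 100}% (inner selection by mean validation F1; per-fold
min–max scaling fit on the learning set only). Modal choices across outer
folds give the consensus estimator, which phase 2 re-evaluates on every other
metric without re-tuning. For linear kernels the fold-averaged coefficients
$\bar w$ of the discriminant hyperplane, rectified and min–max normalized,
form a $[0,1]$ voxel-relevance map.

**Concordance.** Per metric, Pearson's $r$ and the 1-D Wasserstein distance
between the weight map and the FWE-corrected $p$-map over the same voxels —
informative voxels have low $p$ and high weight, so $r < 0$ where a genuine
effect exists.

**Fusion.** Multi-set regularized linear CCA: projections $W_k$ maximize the
summed pairwise correlations of the variates $A_k = X_k W_k$ subject to
$W_k^{\top}(C_{kk} + c I)W_k = I$ (a generalized eigenproblem, solved in each
view's row space). The regularization $c$ (10 log-spaced values in
$[10^{-4}, 10^{2}]$) and the number of components $D \in 1..5$ are selected
by subject-level cross-validation on held-out between-view correlation. Each
(component, view) variate is screened for group differences with IQR outlier
removal, a two-sided Mann–Whitney U test and Benjamini–Hochberg correction;
components significant in ≥ 2 views are *joint*, in exactly one *unique*
group-discriminative.

## Worked example

```python
from skelfuse import (
    SimConfig, generate_cohort, permutation_fwe, extract_clusters,
    nested_cv_phase1, evaluate_phase2, concordance,
)

cfg = SimConfig(
    n_a=46, n_b=23, grid_shape=(20, 20, 20), skeleton_fraction=0.1,
    metric_names=("dti_fa", "mk"), effect_sizes={"dti_fa": 2.0},
    n_clusters=4, cluster_radius=2.5, latent_views=(), latent_effect=0.0,
    seed=42,
)
ds = generate_cohort(cfg)

res = permutation_fwe(ds, "dti_fa", direction="A<B", n_perm=500, seed=1)
clusters = extract_clusters(res, ds.mask, alpha=0.05)

rep = nested_cv_phase1(ds, "dti_fa", seed=0)
rep2 = evaluate_phase2(ds, "dti_fa", rep.consensus_params, seed=0)
rec = concordance(rep2.weight_map, res.p_corr, "dti_fa")
```

prints (via the accompanying report lines):

```
cohort: N=69, skeleton voxels M=800
significant voxels (p_FWE < 0.05): 42
  cluster size= 13  peak value=0.998  at (7, 17, 18)  p < 0.002
  cluster size= 11  peak value=0.998  at (0, 9, 16)  p < 0.002
  cluster size=  9  peak value=0.998  at (1, 3, 14)  p < 0.002
phase-1 consensus params (C, kernel, % features): (0.1, 'linear', 100.0)
phase-1 scores: accuracy=1.00 precision=1.00 recall=1.00 f1=1.00 auc=1.00
weight/p concordance: r=-0.85 (p=8.4e-227), Wasserstein=0.79
```

Reading: with a planted group decrease of d = 2 in `dti_fa`, the permutation
test localizes significant clusters (the cluster table reports size, peak
value = 1 − corrected p, peak location and corrected p), the nested-CV SVM
separates the groups perfectly and settles on a linear kernel with all
features, and the SVM weight map anti-correlates strongly with the corrected
p-map — high predictive relevance coincides with low p, as expected when both
levels see the same effect.

A command-line interface mirrors the library
(`skelfuse simulate|infer|classify|concord|fuse|run|report`); `skelfuse run`
executes the whole pipeline from a YAML config and writes NIfTI maps, TSV
tables and a JSON manifest.

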