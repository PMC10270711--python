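# Methods

`netclass` implements a multiclass classification framework for brain-network
phenotypes: connectivity features are computed per subject from several
modalities and methods, reduced by group-level statistics with permutation
correction, pruned by stability-aware progressive elimination, and classified
one-vs-rest with tuned gradient-boosted ensembles.  This note documents the
models, the defaults and why they were chosen, what the synthetic cohorts do
and do not emulate, and the numerical choices that matter.

## Connectivity features

**Raw functional metrics.**  Voxel-level maps of four resting-state measures:
global correlation (GCOR, the mean Pearson correlation of a voxel with every
other voxel), local correlation (LCOR, the mean correlation with voxels inside
a spatial kernel; the 30 mm kernel "size" is read as a diameter, i.e. a hard
Euclidean ball of radius 15 mm — a Gaussian-weighted kernel is a known
alternative and is deliberately not the default), ALFF (the root-mean-square
of the band-passed series) and fALFF (the ratio of that RMS to the RMS of the
unfiltered series, defined as 0 when the unfiltered RMS is 0).  Band-pass
filtering is an FFT mask — out-of-band Fourier coefficients are zeroed — so
attenuation is exact and testable rather than an IIR approximation.  The
default band is 0.001–0.09 Hz; the low edge is configurable because both 0.00
and 0.001 Hz appear in common preprocessing conventions.

**ROI-to-ROI connectivity.**  The Fisher-transformed Pearson correlation
between every pair of ROI time series.  r is clipped at 1 − 1e−12 before
`atanh` so that degenerate synthetic inputs (perfectly correlated series)
remain finite; zero-variance ROIs yield zero rows with a warning rather than
NaNs.

**Graph metrics.**  Connectivity matrices are thresholded (functional r > 0.3
keeping positive edges only; FA > 0.2) and treated as undirected weighted
graphs with edge length = 1/weight, the standard brain-connectivity-toolbox
convention.  Six nodal metrics are computed: global efficiency (mean inverse
shortest-path distance, 1/∞ counted as 0), local efficiency (mean global
efficiency of the neighbor-induced subgraph with original weights), degree,
strength, the Onnela weighted clustering coefficient (geometric mean of
triangle weights rescaled by the network maximum), and unnormalized weighted
betweenness centrality with fractional splitting of tied shortest paths
(Brandes accumulation; each unordered pair counted once).  Distances run
through `scipy.sparse.csgraph` and betweenness through `python-igraph`; both
are validated in the test suite against a from-scratch exhaustive
path/triangle enumerator on small graphs (to 1e−9) and against networkx.

## Group-level filter

Each pairwise group contrast uses a pooled-variance two-sample t statistic
per element (pooled rather than Welch, matching the GLM-contrast convention
of standard neuroimaging tools); zero-variance elements get t = 0 with a
warning.

**TFCE.**  Spatially structured statistics (voxel maps, ROI matrices) are
enhanced threshold-free: `enhanced(p) = Σ_h extent(h,p)^E · h^H · dh` with the
standard published defaults E = 0.5, H = 2 and dh = h_max/100, using
26-connectivity on 3D grids and 4-connectivity on matrices.  Negative
statistics are enhanced on the negated map with the sign restored.  The
production path is a numba union-find kernel that grows connected components
while sweeping thresholds from high to low; a `scipy.ndimage` reference
backend computes the identical quantity and the two are cross-checked to
1e−10 in the tests.

**Max-statistic FWE.**  The permutation null is the maximum |enhanced| value
over elements per label permutation; p-values use the add-one estimator
(1 + #{null ≥ observed})/(1 + n_perm), which is valid (super-uniform) under
exchangeability and never exactly zero.  When fewer distinct label
assignments exist than requested permutations, all assignments are
enumerated (with a warning) and the exact p-value is used.  1,000
permutations at α = 0.05 is the default.

**ROI-matrix TFCE.**  Before enhancement, ROIs are reordered by agglomerative
clustering of the observed t-matrix rows (correlation distance, average
linkage) so that similarly affected regions are adjacent.  The observed
ordering is held fixed across permutations: permuting labels only keeps the
enhancement operator identical under the null, which is what makes the
max-statistic calibration argument go through.  Treating the symmetric
matrix as a 2D image double-counts mirrored pairs in the extent; this is a
stated approximation.

**FDR.**  Unstructured element families (nodal graph metrics, tract metrics)
use Benjamini–Hochberg at q = 0.05 via statsmodels, verified exactly against
a literal step-up oracle.

**Cluster features.**  Significant voxel masks are reduced to features by
averaging each subject's map over connected components strictly larger than
50 voxels; features are named by component centroid so naming is stable
across runs.

**Power screen.**  For each contrast the minimum detectable standardized
effect d* at power 0.80 and α = 0.05 is computed from the noncentral t
distribution.  Contrasts with d* > 0.5 (the medium-effect benchmark) are
*warned about* but not dropped by default: at realistic clinical group sizes
(e.g. 99 vs 47) d* is ≈ 0.52, so a hard cutoff would exclude essentially
every contrast a study of this size can run.  `power_exclude=True` restores
the strict behavior.

**Fallback features.**  Under the null (or at small scale) the corrected
filter often selects nothing.  So that every model always has inputs — and
so that null calibration of the *downstream* stages is measurable — each
modality/method falls back to its top-k elements by training-set |t|
(default k = 10), provenance-tagged `fallback`.  Because the ranking uses
training subjects only, this leaks no test information.

## Feature selection

Progressive elimination runs on the training partition only.  Each step fits
a gradient-boosted ensemble (XGBoost) on each of k = 5 stratified folds and
records per-fold validation micro-AUC and per-fold importance vectors.
Importances are `total_gain` — the loss-reduction analogue of impurity
("Gini") decrease, which is what a regularized boosted ensemble exposes —
normalized to sum 1 per fold.  The lowest-importance ⌈0.10·m⌉ features (ties
broken by name) are dropped per step until one feature remains.  The 10%
step is a compromise between trace resolution and cost.

Rank stability is assessed per step: a feature is *stable* when ordering
features by the upper (right-tail) bound of their fold-wise t-interval
(default 95%) reproduces the ordering by mean importance at that feature's
position.  The optimal feature count N is the smallest retained-set size
whose mean validation micro-AUC is within 0.005 AUC of the trace maximum
("fails to improve" quantified as 0.005, about an order of magnitude below
fold-to-fold noise at these sample sizes).

Elimination runs once per model on the multiclass training labels
(multi-class XGBoost importances) rather than once per one-vs-rest binary
subproblem.  This yields a single interpretable feature list per model and
is six times cheaper; per-class elimination would allow class-specific
feature sets at the cost of comparability.

## Classification and evaluation

Each model decomposes the multiclass problem into one binary dataset per
class (the class of interest vs everyone else) and fits one XGBoost
classifier per class.  Seven hyperparameters (number of trees, maximum
depth, learning rate, minimum split loss, maximum leaves, L1 and L2 weights)
are tuned per class by Bayesian optimization — a Gaussian-process surrogate
(Matérn-5/2 kernel on the unit-cube rescaling of the space, log-scaled
ranges where appropriate) with expected-improvement acquisition and 5 seeded
random initial points — maximizing mean k-fold validation AUC within the
training partition.  The outer 80/20 split is stratified and fixed before
any filtering or selection, so test subjects never influence masks,
importances or N.

AUC is computed as the Mann–Whitney pair-counting probability (ties counted
1/2) via the rank formula; the micro-average AUC concatenates all classes'
(score, one-vs-rest label) pairs into one binary problem, weighting samples
and labels equally under class imbalance.  Macro-average AUC is reported
alongside.  Confidence intervals on validation AUC are t-intervals over the
outer folds of the selected elimination step (a bootstrap CI is the obvious
alternative; the fold interval is cheaper and is flagged in the report
metadata).  Accuracy, sensitivity, specificity and F1 come from the argmax
class over the one-vs-rest scores, macro-averaged.

Two classifiers' ROC curves on the same subjects are compared by the
integrated absolute difference between the curves over the union grid of
observed false-positive rates.  The reference distribution pools both score
vectors, ranks them jointly, and swaps each subject's rank pair with
probability 1/2 — subject-level exchangeability of the two classifiers under
the null.  Add-one p-values again.

## The 14-model experiment

2 modalities × 3 methods + 1 multimodal combination, each with and without
the five demographic/cognitive covariates (age, sex, education, CDR, MMSE)
= 14 models.  The pipeline fans one master seed out to per-stage child
streams (cohort, split, filter, per-model selection/training, comparisons)
via `numpy.random.SeedSequence` spawning, so any stage is reproducible
independent of execution order; a rerun with the same config is
bit-identical and the run manifest records the config snapshot and a result
checksum.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the physics of MRI:

* **ROI time series** are multivariate normal draws from a subject-specific
  correlation matrix: a latent-factor base structure (positive definite by
  construction), shifted on the Fisher-z scale by the group's planted edge
  deltas plus subject-level edge noise (σ = 0.05), then projected to the
  nearest positive-definite correlation matrix by eigenvalue clipping.  A
  planted effect of size d shifts the group mean by d times the expected
  between-subject SD of the measured edge z (subject noise plus 1/√(T−3)
  sampling noise), so realized Cohen's d matches the requested d.
* **Voxel maps** are i.i.d. standard-normal backgrounds with spherical
  clusters shifted by d for affected groups — surrogates for metric maps,
  not filtered BOLD; they carry no spatial autocorrelation, so cluster
  sizes under the null are smaller than in smoothed real data.
* **Structural data** are symmetric FA-like matrices in [0, 1] with zero
  diagonal plus a 7-metric per-tract table (FA/AD/RD/MD/NQA/ISO/RDI
  surrogates on a common unit scale); 40 tracts by default (desk scale —
  atlas-level tract granularity is out of scope).
* **Covariates** follow published clinical descriptives per group (medians
  and median absolute deviations for age, education, CDR, MMSE; female
  fraction for sex, coded 1 = female).  CDR is a latent normal snapped to
  the clinical scale {0, 0.5, 1, 2, 3}; MMSE is rounded and clipped to
  [0, 30]; MAD is converted to a normal σ by the 1.4826 factor.  Default
  group sizes are 99/47/38/34/42/38 (healthy controls plus five variants).

Because the generator is exchangeable across groups when the effect plan is
empty and covariate plans are equal, null calibration of every downstream
stage is a meaningful test.  What passing tests do *not* show: robustness to
spatially autocorrelated noise, scanner effects, motion artifacts,
non-Gaussian BOLD distributions, or atrophy-driven confounds between
covariates and connectivity — none of which the generator produces.

## Numerical choices and degenerate inputs

* Pearson r clipped to ±(1 − 1e−12) before Fisher transform; zero-variance
  voxels/ROIs give 0 with a warning.
* TFCE uses right-Riemann steps at dh = h_max/100 by default; the
  acceptance suite verifies agreement with dh = h_max/10⁴ integration.
* Elimination ties (equal mean importance) break by feature name; feature
  naming is deterministic (cluster centroids, edge indices), so reruns are
  stable.
* Empty masks, single-label classes, singleton graphs and constant features
  degrade to explicit, documented values (empty feature frames with a
  warning, NaN AUC with a note, all-zero metrics, zero importance) rather
  than errors.
* All stochastic components consume `numpy.random.Generator` streams derived
  from explicit seeds; nothing touches global random state.

## Problem sizes used by the test and acceptance runs

The suite exercises the pipeline at reduced scale, chosen for statistical
identifiability of each check: null end-to-end calibration uses three groups
of 330 subjects so the total null standard deviation of test micro-AUC
(~0.026, test-set sampling plus boosted-tree score variance) makes the
[0.4, 0.6] acceptance band a ≈4σ statement; family-wise error
calibration uses 200 null cohorts of 20+20 subjects on a 12³ grid with 200
permutations; feature recovery uses 400 candidate features with 5 planted at
d = 1.5 and 40 subjects per group.  The acceptance script runs the full
14-model experiment on a 360-subject cohort with planted functional,
structural and voxel-level effects at 10 ROIs and an 8³ grid.

## Known limitations

* The ROI-matrix TFCE construction (reordered matrix as a 2D image) is one
  of several plausible parametrizations of matrix-neighborhood enhancement.
* LCOR uses a hard spherical kernel; Gaussian weighting would change values
  near cluster edges.
* The seventh commonly listed nodal graph metric family (e.g. participation
  or eigenvector measures) is not included; the six implemented are the
  enumerated standard set.
* Per-class (rather than per-model) feature elimination, covariate-adjusted
  GLM filtering, and alternative learners are out of scope.
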