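# netclass

Multiclass classification of brain-network phenotypes from multimodal
connectivity features.

## The problem

Distinguishing one neurodegenerative phenotype from *several* related ones
simultaneously (for example, a frontotemporal-dementia variant against four
other variants plus healthy controls) is much harder than the usual binary
patient-vs-control setup: the groups share overlapping pathophysiology and
any one imaging modality sees only part of the picture.  `netclass`
implements a complete, testable pipeline for this problem:

1. **Connectivity features** from two modalities × three methods:
   voxel-level functional metrics (GCOR, LCOR, ALFF, fALFF), Fisher-z
   ROI-to-ROI matrices, and six nodal weighted-graph metrics (global and
   local efficiency, degree, strength, clustering coefficient, betweenness
   centrality) on thresholded functional (r > 0.3) and structural FA
   (> 0.2) networks, plus tract-level diffusion metric tables.
2. **Group-level filter**: pooled-variance t statistics per element with
   threshold-free cluster enhancement (TFCE,
   `Σ_h extent(h)^E · h^H · dh`, E = 0.5, H = 2) and max-statistic
   permutation FWE control for spatial elements, Benjamini–Hochberg FDR for
   unstructured ones, and cluster averaging (> 50 voxels) into features.
3. **Stability-aware progressive elimination** under nested 5-fold
   cross-validation: per-fold boosted-ensemble importances, fold-to-fold
   rank-stability checks, and selection of the optimal feature count N
   (the smallest set within 0.005 AUC of the best).
4. **One-vs-rest classification** with XGBoost, hyperparameters tuned per
   class by Gaussian-process Bayesian optimization (Matérn-5/2 surrogate,
   expected improvement), evaluated on a held-out stratified 20% test set by
   micro-average ROC AUC — the AUC of the pooled (score, one-vs-rest label)
   pairs, `AUC = P(score_pos > score_neg) + ½·P(tie)`.
5. **The 14-model experiment**: {functional, structural} × {raw, ROI,
   graph} + multimodal, each with and without demographic/cognitive
   covariates (age, sex, education, CDR, MMSE), plus permutation comparison
   of the resulting ROC curves.

Because real clinical MRI cohorts are access-restricted, the package ships a
first-class synthetic cohort generator with *planted* group effects (edges,
voxel clusters, tracts, covariate shifts, each with a standardized effect
size d) and a ground-truth record, so every stage can be validated by
recovery and null-calibration experiments.  See `docs/methods.md` for the
full model description and assumptions.

## Worked example

```python
import numpy as np
from netclass import CohortSpec, PlantedEffect, PipelineConfig, run_pipeline

spec = CohortSpec(
    group_names=("HC", "bvFTD", "svPPA"),
    group_sizes=(120, 120, 120),
    n_roi=10, grid_dims=(8, 8, 8), n_timepoints=60, n_tracts=12,
    effect_plan=(
        PlantedEffect("functional", ("edge", 0, 1), ("bvFTD",), -1.5),
        PlantedEffect("voxelmap", ("voxel", (2, 2, 2), 2), ("bvFTD",), 1.2, "gcor"),
        PlantedEffect("structural", ("tract", 2), ("svPPA",), -1.2),
    ),
)
config = PipelineConfig(
    cohort_spec=spec, n_permutations_imaging=60, bo_iterations=3,
    models=("functional_raw", "functional_raw_cov", "multimodal_cov"), seed=7,
)
result = run_pipeline(config)
print(result.metrics_table().round(3))
```

prints (seed 7):

```
                    accuracy  sensitivity  specificity     f1  micro_auc
model
functional_raw         0.528        0.528        0.764  0.503      0.708
functional_raw_cov     0.792        0.792        0.896  0.785      0.924
multimodal_cov         0.944        0.944        0.972  0.945      0.979
```

Reading the output: raw functional connectivity alone carries the planted
edge/cluster signal (micro-AUC 0.71 against a 0.5 chance level on three
balanced classes); adding the cognitive covariates — whose group medians
differ by design, mirroring clinical descriptives — lifts it to 0.92, and
the multimodal model that also sees the planted structural effects reaches
0.98.  `result.reports[key].selected_features` lists the optimal feature
set with provenance tags, and `result.comparisons` holds the
pooled-rank-permutation p-values comparing each model's ROC curve with the
best model's.

A thin CLI wraps the same functions:

```bash
netclass simulate --config config.yaml --seed 3 --out cohort/
netclass run --config config.yaml --models multimodal_cov --out results/
```

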