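"""End-to-end orchestration of the 14-model classification experiment.

The experiment crosses two connectivity modalities (functional, structural)
with three methods (raw / voxel- or tract-level, ROI-to-ROI, graph
metrics), adds one multimodal combination, and runs each of the seven
resulting feature sets with and without demographic/cognitive covariates —
14 models in total.  For every model the pipeline: builds features from the
group-level filter (computed on the training partition only), runs
stability-aware progressive elimination to pick the optimal feature count,
fits a one-vs-rest boosted ensemble with Bayesian hyperparameter tuning,
and evaluates ROC performance on the held-out test partition.  All
randomness fans out from one master seed via named child streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .classify import (
    auc_confidence_interval,
    compare_rocs,
    default_space,
    fit_ovr_ensemble,
    roc_and_auc,
    stratified_holdout_split,
)
from .cohort import (
    Cohort,
    CohortSpec,
    GroundTruth,
    TRACT_METRICS,
    VOXELMAP_METRICS,
    generate_cohort,
)
from .filtering import (
    GroupDesign,
    TFCEParams,
    detectable_effect_filter,
    extract_cluster_features,
    fdr_bh,
    mass_univariate_t,
    permutation_fwe,
    roi_matrix_tfce,
    t_pvalues,
)
from .functional import roi_connectivity
from .graphs import METRIC_NAMES, nodal_graph_metrics, threshold_adjacency
from .io import write_json
from .rfe import FeatureTable, progressive_elimination, select_optimal_n

__all__ = [
    "PipelineConfig",
    "ModelReport",
    "PipelineResult",
    "MODEL_KEYS",
    "run_pipeline",
    "render_report",
]

_BASE_MODELS = (
    ("functional", "raw"),
    ("functional", "roi"),
    ("functional", "graph"),
    ("structural", "raw"),
    ("structural", "roi"),
    ("structural", "graph"),
    ("multimodal", "all"),
)

#: The 14 model keys: 2 modalities x 3 methods + 1 multimodal, each with and
#: without demographic/cognitive covariates.
MODEL_KEYS = tuple(
    (mod if mod == "multimodal" else f"{mod}_{meth}") + ("_cov" if cov else "")
    for (mod, meth), cov in itertools.product(_BASE_MODELS, (False, True))
)


@dataclass
class PipelineConfig:
    """Configuration of one experiment run.

    Defaults follow the study constants: functional edge threshold 0.3, FA
    threshold 0.2, band 0.001-0.09 Hz, minimum cluster size 50 voxels,
    k = 5 folds, 80/20 train/test split, 1,000 imaging permutations and
    5,000 for median tests, power threshold 0.80.
    """

    cohort_spec: CohortSpec | None = None
    cohort_dir: str | None = None
    functional_threshold: float = 0.3
    fa_threshold: float = 0.2
    band: tuple[float, float] = (0.001, 0.09)
    n_permutations_imaging: int = 1000
    n_permutations_median: int = 5000
    n_permutations_roc: int = 500
    alpha: float = 0.05
    fdr_q: float = 0.05
    min_cluster_size: int = 50
    k_folds: int = 5
    test_fraction: float = 0.2
    drop_fraction: float = 0.10
    plateau_tolerance: float = 0.005
    ci_level: float = 0.95
    bo_iterations: int = 20
    fallback_k: int = 10
    power_threshold: float = 0.80
    power_exclude: bool = False
    models: tuple[str, ...] | None = None
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cohort_spec is None and self.cohort_dir is None:
            raise ValueError("cohort_spec: a cohort spec or cohort_dir is required")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction: must be in (0, 1)")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction: must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds: must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha: must be in (0, 1)")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q: must be in (0, 1)")
        if self.n_permutations_imaging < 1:
            raise ValueError("n_permutations_imaging: must be >= 1")
        if self.min_cluster_size < 0:
            raise ValueError("min_cluster_size: must be >= 0")
        if self.bo_iterations < 1:
            raise ValueError("bo_iterations: must be >= 1")
        if self.fallback_k < 1:
            raise ValueError("fallback_k: must be >= 1")
        if self.models is not None:
            unknown = [m for m in self.models if m not in MODEL_KEYS]
            if unknown:
                raise ValueError(f"models: unknown model keys {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec_raw = raw.pop("cohort_spec", None)
        if spec_raw is not None:
            from .io import _spec_from_dict

            defaults = dataclasses.asdict(CohortSpec())
            defaults.pop("covariate_plan")
            defaults.pop("effect_plan")
            base = _spec_from_dict(
                {
                    **{
                        "covariate_plan": spec_raw.pop(
                            "covariate_plan",
                            {
                                g: dataclasses.asdict(p)
                                for g, p in CohortSpec().covariate_plan.items()
                            },
                        ),
                        "effect_plan": spec_raw.pop("effect_plan", []),
                    },
                    **{**defaults, **spec_raw},
                }
            )
            raw["cohort_spec"] = base
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "models" in raw and raw["models"] is not None:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort_spec is not None:
            from .io import _spec_to_dict

            d["cohort_spec"] = _spec_to_dict(self.cohort_spec)
        return d


@dataclass
class ModelReport:
    """Evaluation of one of the 14 models."""

    key: str
    modality: str
    method: str
    with_covariates: bool
    n_candidate_features: int
    optimal_n: int
    selected_features: tuple[str, ...]
    provenance: dict[str, str]
    micro_auc: float
    macro_auc: float
    per_class_auc: dict
    val_auc_mean: float
    val_auc_ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    chosen_params: dict
    top_features: list[tuple[str, float]]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["selected_features"] = list(self.selected_features)
        return d


@dataclass
class PipelineResult:
    reports: dict[str, ModelReport]
    comparisons: pd.DataFrame
    config: PipelineConfig
    manifest: dict
    truth: GroundTruth | None = None

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for key, rep in self.reports.items():
            rows.append(
                {
                    "model": key,
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "f1": rep.f1,
                    "micro_auc": rep.micro_auc,
                }
            )
        return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# feature builders (filter statistics on the training partition only)
# ---------------------------------------------------------------------------


def _contrast_pairs(groups: np.ndarray) -> list[tuple[str, str]]:
    present = list(dict.fromkeys(groups))
    return list(itertools.combinations(present, 2))


def _power_check(labels: np.ndarray, pairs, config: PipelineConfig) -> list[tuple[str, str]]:
    """Warn about (optionally drop) contrasts whose minimum detectable effect
    exceeds the medium-effect benchmark d = 0.5."""
    kept = []
    for a, b in pairs:
        n1 = int((labels == a).sum())
        n2 = int((labels == b).sum())
        d_star = detectable_effect_filter(n1, n2, config.power_threshold, config.alpha)
        if d_star > 0.5:
            warnings.warn(
                f"contrast {a} vs {b} (n={n1}/{n2}) underpowered for medium effects "
                f"(minimum detectable d = {d_star:.2f})"
            )
            if config.power_exclude:
                continue
        kept.append((a, b))
    return kept


def _tfce_params(config: PipelineConfig, connectivity: int) -> TFCEParams:
    return TFCEParams(
        n_permutations=config.n_permutations_imaging,
        alpha=config.alpha,
        connectivity=connectivity,
    )


def _fallback_table(
    values: np.ndarray,
    names: list[str],
    train_rows: np.ndarray,
    labels_train: np.ndarray,
    pairs,
    k: int,
    prefix: str,
) -> pd.DataFrame:
    """Top-k elements by training-set |t| across contrasts; used when the
    corrected filter selects nothing so every model still has inputs."""
    best = np.zeros(values.shape[1])
    for a, b in pairs:
        design = GroupDesign(labels_train, a, b)
        t = mass_univariate_t(values[train_rows], design, warn=False)
        best = np.maximum(best, np.abs(t))
    top = np.argsort(-best, kind="stable")[: min(k, values.shape[1])]
    top = top[np.argsort(top)]
    return pd.DataFrame({f"{prefix}_fb_{names[i]}": values[:, i] for i in top})


def _seeded(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31 - 1))


def _build_voxel_features(cohort, train_rows, labels_train, pairs, config, seed_seq):
    grid = cohort.spec.grid_dims
    frames = []
    seeds = seed_seq.spawn(len(VOXELMAP_METRICS))
    fallback_sources = []
    for metric, mseq in zip(VOXELMAP_METRICS, seeds):
        stack = np.stack([cohort.voxel_maps[s][metric] for s in cohort.subject_ids])
        union = np.zeros(grid, dtype=bool)
        for (a, b), cseq in zip(pairs, mseq.spawn(len(pairs))):
            design = GroupDesign(labels_train, a, b)
            res = permutation_fwe(
                stack[train_rows], design, _tfce_params(config, 26), seed=_seeded(cseq)
            )
            union |= res.mask
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = extract_cluster_features(
                stack, union, config.min_cluster_size, prefix=f"fraw_{metric}"
            )
        if not feats.empty:
            frames.append(feats)
        fallback_sources.append((metric, stack.reshape(stack.shape[0], -1)))
    if frames:
        data = pd.concat(frames, axis=1)
    else:
        per_metric = max(1, config.fallback_k // len(fallback_sources))
        data = pd.concat(
            [
                _fallback_table(
                    flat,
                    [str(i) for i in range(flat.shape[1])],
                    train_rows,
                    labels_train,
                    pairs,
                    per_metric,
                    f"fraw_{metric}",
                )
                for metric, flat in fallback_sources
            ],
            axis=1,
        )
    data.index = cohort.subject_ids
    tag = "func_raw"
    return FeatureTable(data, {c: tag for c in data.columns})


def _edge_features(stacks, subject_ids, mask, prefix):
    iu, ju = np.nonzero(np.triu(mask, 1))
    data = pd.DataFrame(
        {f"{prefix}_{i}_{j}": stacks[:, i, j] for i, j in zip(iu, ju)}
    )
    data.index = subject_ids
    return data


def _build_matrix_features(
    stacks, cohort, train_rows, labels_train, pairs, config, seed_seq, prefix, tag
):
    r = stacks.shape[1]
    union = np.zeros((r, r), dtype=bool)
    for (a, b), cseq in zip(pairs, seed_seq.spawn(len(pairs))):
        design = GroupDesign(labels_train, a, b)
        res = roi_matrix_tfce(
            stacks[train_rows], design, _tfce_params(config, 4), seed=_seeded(cseq)
        )
        union |= res.mask
    data = _edge_features(stacks, cohort.subject_ids, union, prefix)
    if data.empty:
        iu, ju = np.triu_indices(r, 1)
        flat = stacks[:, iu, ju]
        names = [f"{i}_{j}" for i, j in zip(iu, ju)]
        data = _fallback_table(
            flat, names, train_rows, labels_train, pairs, config.fallback_k, prefix
        )
        data.index = cohort.subject_ids
    return FeatureTable(data, {c: tag for c in data.columns})


def _build_columnwise_features(
    values, names, cohort, train_rows, labels_train, pairs, config, prefix, tag
):
    """Mass-univariate t + BH-FDR per contrast on unstructured columns."""
    union = np.zeros(values.shape[1], dtype=bool)
    for a, b in pairs:
        design = GroupDesign(labels_train, a, b)
        t = mass_univariate_t(values[train_rows], design, warn=False)
        n1 = int((labels_train == a).sum())
        n2 = int((labels_train == b).sum())
        union |= fdr_bh(t_pvalues(t, n1 + n2 - 2), config.fdr_q)
    if union.any():
        cols = np.flatnonzero(union)
        data = pd.DataFrame(
            {f"{prefix}_{names[i]}": values[:, i] for i in cols}, index=cohort.subject_ids
        )
    else:
        data = _fallback_table(
            values, names, train_rows, labels_train, pairs, config.fallback_k, prefix
        )
        data.index = cohort.subject_ids
    return FeatureTable(data, {c: tag for c in data.columns})


def _nodal_metric_matrix(matrices: dict, subject_ids, threshold: float) -> tuple[np.ndarray, list[str]]:
    rows = []
    names = None
    for sid in subject_ids:
        graph = threshold_adjacency(matrices[sid], threshold, positive_only=True)
        metrics = nodal_graph_metrics(graph)
        if names is None:
            names = [f"{m}_{n}" for m in METRIC_NAMES for n in range(metrics.shape[0])]
        rows.append(metrics.to_numpy().T.ravel())
    return np.asarray(rows), names


def build_feature_tables(
    cohort: Cohort, train_ids, config: PipelineConfig, seed_seq: np.random.SeedSequence
) -> dict[str, FeatureTable]:
    """All six modality/method feature tables plus the covariate table.

    Filter statistics (TFCE-FWE or FDR) use only the training subjects; the
    resulting masks are applied to every subject's data.
    """
    ids = cohort.subject_ids
    train_rows = np.array([sid in set(train_ids) for sid in ids])
    labels = cohort.subjects["group"].to_numpy()
    labels_train = labels[train_rows]  # aligned with values[train_rows]
    pairs = _power_check(labels_train, _contrast_pairs(labels_train), config)
    seqs = seed_seq.spawn(4)

    tables: dict[str, FeatureTable] = {}
    tables["functional_raw"] = _build_voxel_features(
        cohort, train_rows, labels_train, pairs, config, seqs[0]
    )

    z_stack = np.stack([roi_connectivity(cohort.roi_timeseries[s]) for s in ids])
    tables["functional_roi"] = _build_matrix_features(
        z_stack, cohort, train_rows, labels_train, pairs, config, seqs[1], "froi", "func_roi"
    )

    r_mats = {sid: np.tanh(z) for sid, z in zip(ids, z_stack)}
    fg_vals, fg_names = _nodal_metric_matrix(r_mats, ids, config.functional_threshold)
    tables["functional_graph"] = _build_columnwise_features(
        fg_vals, fg_names, cohort, train_rows, labels_train, pairs, config, "fgraph", "func_graph"
    )

    tract_vals = np.stack(
        [cohort.tract_metrics[s].to_numpy().ravel() for s in ids]
    )
    tract_names = [
        f"{m}_{t}" for t in range(cohort.spec.n_tracts) for m in TRACT_METRICS
    ]
    tables["structural_raw"] = _build_columnwise_features(
        tract_vals, tract_names, cohort, train_rows, labels_train, pairs, config, "sraw", "struct_raw"
    )

    fa_stack = np.stack([cohort.fa_matrices[s] for s in ids])
    tables["structural_roi"] = _build_matrix_features(
        fa_stack, cohort, train_rows, labels_train, pairs, config, seqs[2], "sroi", "struct_roi"
    )

    sg_vals, sg_names = _nodal_metric_matrix(
        cohort.fa_matrices, ids, config.fa_threshold
    )
    tables["structural_graph"] = _build_columnwise_features(
        sg_vals, sg_names, cohort, train_rows, labels_train, pairs, config, "sgraph", "struct_graph"
    )

    cov = cohort.subjects.set_index("subject_id")[
        ["age", "sex", "education", "cdr", "mmse"]
    ].astype(float)
    tables["covariates"] = FeatureTable(cov, {c: "covariate" for c in cov.columns})
    return tables


# ---------------------------------------------------------------------------
# model fitting and evaluation
# ---------------------------------------------------------------------------


def _model_table(tables: dict[str, FeatureTable], modality: str, method: str, cov: bool):
    if modality == "multimodal":
        parts = [tables[f"{m}_{meth}"] for m, meth in _BASE_MODELS[:-1]]
    else:
        parts = [tables[f"{modality}_{method}"]]
    if cov:
        parts.append(tables["covariates"])
    return FeatureTable.concat(parts)


def _classification_metrics(y_true, y_pred, classes) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    acc = float((y_true == y_pred).mean())
    sens, spec, f1s = [], [], []
    for cls in classes:
        tp = np.sum((y_true == cls) & (y_pred == cls))
        fn = np.sum((y_true == cls) & (y_pred != cls))
        fp = np.sum((y_true != cls) & (y_pred == cls))
        tn = np.sum((y_true != cls) & (y_pred != cls))
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
        f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan)
    return {
        "accuracy": acc,
        "sensitivity": float(np.nanmean(sens)),
        "specificity": float(np.nanmean(spec)),
        "f1": float(np.nanmean(f1s)),
    }


def _fit_and_evaluate(
    key: str,
    table: FeatureTable,
    cohort: Cohort,
    train_ids,
    test_ids,
    config: PipelineConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[ModelReport, np.ndarray]:
    modality, method, cov = _parse_key(key)
    y = dict(zip(cohort.subjects["subject_id"], cohort.subjects["group"]))
    y_train = np.array([y[s] for s in train_ids])
    y_test = np.array([y[s] for s in test_ids])
    X_train = table.data.loc[train_ids]
    X_test = table.data.loc[test_ids]
    notes = []

    rfe_seed, fit_seed = (_seeded(s) for s in seed_seq.spawn(2))
    if X_train.shape[1] >= 2:
        trace = progressive_elimination(
            X_train,
            y_train,
            k=config.k_folds,
            drop_fraction=config.drop_fraction,
            seed=rfe_seed,
            ci_level=config.ci_level,
        )
        optimal_n, selected = select_optimal_n(trace, config.plateau_tolerance)
        chosen_step = next(s for s in trace.steps if s.n_features == optimal_n)
        val_mean, val_lo, val_hi = auc_confidence_interval(chosen_step.fold_aucs)
    else:
        selected = tuple(table.feature_names)
        optimal_n = len(selected)
        val_mean, val_lo, val_hi = float("nan"), float("nan"), float("nan")
        notes.append("single candidate feature; elimination skipped")

    model = fit_ovr_ensemble(
        X_train[list(selected)],
        y_train,
        space=default_space(),
        k=config.k_folds,
        seed=fit_seed,
        n_bo_iterations=config.bo_iterations,
    )
    scores = model.predict_scores(X_test[list(selected)])
    roc = roc_and_auc(scores, y_test, model.classes)
    pred = np.asarray(model.classes)[np.argmax(scores, axis=1)]
    cls_metrics = _classification_metrics(y_test, pred, model.classes)

    imp = model.importances().mean(axis=0).sort_values(ascending=False)
    report = ModelReport(
        key=key,
        modality=modality,
        method=method,
        with_covariates=cov,
        n_candidate_features=table.data.shape[1],
        optimal_n=optimal_n,
        selected_features=tuple(selected),
        provenance={n: table.provenance[n] for n in selected},
        micro_auc=roc.micro_auc,
        macro_auc=roc.macro_auc,
        per_class_auc={str(k_): v for k_, v in roc.per_class_auc.items()},
        val_auc_mean=val_mean,
        val_auc_ci=(val_lo, val_hi),
        chosen_params={str(c): p for c, p in model.chosen_params.items()},
        top_features=[(n, float(v)) for n, v in imp.head(10).items()],
        notes=notes + roc.notes,
        **cls_metrics,
    )
    # pooled one-vs-rest scores/labels for cross-model ROC comparison
    pooled_scores = scores.T.ravel()
    return report, pooled_scores


def _parse_key(key: str) -> tuple[str, str, bool]:
    cov = key.endswith("_cov")
    base = key[:-4] if cov else key
    if base == "multimodal":
        return "multimodal", "all", cov
    modality, method = base.split("_", 1)
    return modality, method, cov


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run cohort building, filtering, selection, training and evaluation
    for every requested model; returns reports plus a cross-model
    ROC-comparison table."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    seq_cohort, seq_split, seq_filter, seq_models, seq_roc = master.spawn(5)

    truth = None
    if config.cohort_dir is not None:
        from .io import read_cohort

        cohort = read_cohort(config.cohort_dir)
    else:
        spec = dataclasses.replace(config.cohort_spec, seed=_seeded(seq_cohort))
        cohort, truth = generate_cohort(spec)

    y_all = cohort.subjects["group"].to_numpy()
    train_ids, test_ids = stratified_holdout_split(
        cohort.subject_ids, y_all, config.test_fraction, seed=_seeded(seq_split)
    )

    tables = build_feature_tables(cohort, train_ids, config, seq_filter)

    keys = config.models if config.models is not None else MODEL_KEYS
    reports: dict[str, ModelReport] = {}
    pooled: dict[str, np.ndarray] = {}
    model_seqs = dict(zip(MODEL_KEYS, seq_models.spawn(len(MODEL_KEYS))))
    for key in keys:
        modality, method, cov = _parse_key(key)
        table = _model_table(tables, modality, method, cov)
        reports[key], pooled[key] = _fit_and_evaluate(
            key, table, cohort, train_ids, test_ids, config, model_seqs[key]
        )

    y_test = cohort.groups_of(test_ids)
    classes = list(np.unique(y_all))
    pooled_labels = np.concatenate([y_test == c for c in classes])
    comparisons = _compare_models(reports, pooled, pooled_labels, config, seq_roc)

    manifest = _manifest(config, reports)
    result = PipelineResult(
        reports=reports,
        comparisons=comparisons,
        config=config,
        manifest=manifest,
        truth=truth,
    )
    if config.out_dir is not None:
        _write_outputs(result)
    return result


def _compare_models(reports, pooled, pooled_labels, config, seq) -> pd.DataFrame:
    if len(reports) < 2:
        return pd.DataFrame(columns=["model_a", "model_b", "statistic", "p_value"])
    best = max(reports, key=lambda k: np.nan_to_num(reports[k].micro_auc))
    rows = []
    for key, cseq in zip(reports, seq.spawn(len(reports))):
        if key == best:
            continue
        p, stat = compare_rocs(
            pooled[best],
            pooled[key],
            pooled_labels,
            n_permutations=config.n_permutations_roc,
            seed=_seeded(cseq),
        )
        rows.append(
            {"model_a": best, "model_b": key, "statistic": stat, "p_value": p}
        )
    return pd.DataFrame(rows)


def _manifest(config: PipelineConfig, reports) -> dict:
    snap = config.snapshot()
    digest = hashlib.sha256(
        repr(sorted((k, r.micro_auc) for k, r in reports.items())).encode()
    ).hexdigest()
    return {
        "package_version": _version,
        "config": snap,
        "master_seed": config.seed,
        "results_checksum": digest,
    }


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics_table().to_csv(out / "model_metrics.csv")
    result.comparisons.to_csv(out / "roc_comparisons.csv", index=False)
    write_json(
        out / "model_reports.json", {k: r.to_dict() for k, r in result.reports.items()}
    )
    write_json(out / "manifest.json", result.manifest)
    (out / "report.txt").write_text(render_report(result))


def render_report(result: PipelineResult) -> str:
    """Human-readable summary: per-model table of accuracy, sensitivity,
    specificity, F1 and micro-average AUC, plus top selected features."""
    if not result.reports:
        raise ValueError("empty results bundle")
    lines = ["Model performance (test partition)", ""]
    lines.append(result.metrics_table().round(3).to_string())
    lines.append("")
    for key in sorted(result.reports):
        rep = result.reports[key]
        lines.append(f"{key}: optimal N = {rep.optimal_n}")
        if rep.top_features:
            for name, val in rep.top_features[:5]:
                tag = rep.provenance.get(name, "?")
                lines.append(f"  {name} [{tag}] importance {val:.3f}")
        else:
            lines.append("  no features selected")
    if not result.comparisons.empty:
        lines.append("")
        lines.append("ROC-curve comparisons against the best model:")
        lines.append(result.comparisons.round(4).to_string(index=False))
    return "\n".join(lines) + "\n"
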