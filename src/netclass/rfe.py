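"""Stability-aware progressive feature elimination under nested k-folds.

At each iteration a boosted-tree ensemble is fitted on each of k stratified
folds of the training partition; per-fold validation micro-AUC and per-fold
importance vectors (total-gain, the tree-ensemble impurity-decrease
analogue) are recorded, the ranking stability of every feature is assessed
from the fold-to-fold confidence interval of its importance, and the
lowest-importance fraction of features is dropped.  The optimal feature
count N is the smallest retained-set size whose mean validation micro-AUC
is within a tolerance of the best step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classify import gain_importances, make_classifier, micro_average_auc

__all__ = [
    "FeatureTable",
    "EliminationStep",
    "EliminationTrace",
    "foldwise_importances",
    "stability_check",
    "progressive_elimination",
    "select_optimal_n",
]


@dataclass
class FeatureTable:
    """Subjects x named features with a provenance tag per feature.

    Provenance tags name the source of each column (modality/method, e.g.
    ``"func_raw"``, or ``"covariate"``), so selected features remain
    interpretable downstream.
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")
        for col in self.data.columns:
            self.provenance.setdefault(col, "unknown")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        names = list(names)
        return FeatureTable(self.data[names].copy(), {n: self.provenance[n] for n in names})

    @classmethod
    def concat(cls, tables: Sequence["FeatureTable"]) -> "FeatureTable":
        frames = [t.data for t in tables]
        prov: dict[str, str] = {}
        for t in tables:
            prov.update(t.provenance)
        return cls(pd.concat(frames, axis=1), prov)


@dataclass
class EliminationStep:
    features: tuple[str, ...]
    fold_aucs: np.ndarray
    importances: pd.DataFrame  # folds x features
    stability: pd.DataFrame

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def mean_auc(self) -> float:
        vals = self.fold_aucs[~np.isnan(self.fold_aucs)]
        return float(vals.mean()) if vals.size else float("nan")


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("trace must have at least one step")
        sizes = [s.n_features for s in self.steps]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("feature counts must be strictly decreasing")

    def sizes(self) -> list[int]:
        return [s.n_features for s in self.steps]

    def mean_aucs(self) -> list[float]:
        return [s.mean_auc for s in self.steps]


def _fold_run(X: pd.DataFrame, y: np.ndarray, k: int, seed: int, model_params):
    """Fit one booster per stratified fold; return (importances, aucs)."""
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"classes smaller than k={k}: {small.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    imps = np.zeros((k, X.shape[1]))
    aucs = np.full(k, np.nan)
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        model = make_classifier(model_params, seed=seed + fold)
        model.fit(X.iloc[tr], _encode(y[tr], classes))
        imps[fold] = gain_importances(model, list(X.columns))
        scores = model.predict_proba(X.iloc[va])
        if scores.shape[1] == 1:  # degenerate fold with one class present
            continue
        aucs[fold] = micro_average_auc(scores, _encode(y[va], classes), np.arange(len(classes)))
    return pd.DataFrame(imps, columns=list(X.columns)), aucs


def _encode(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[v] for v in y])


def foldwise_importances(
    X: FeatureTable | pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
    model_params: dict | None = None,
) -> pd.DataFrame:
    """Per-fold normalized importance vectors (folds x features).

    A boosted-tree ensemble is trained on each of k stratified folds
    (training on the other k-1); importances are total-gain, normalized to
    sum 1 within a fold.
    """
    data = X.data if isinstance(X, FeatureTable) else X
    imps, _ = _fold_run(data, np.asarray(y), k, seed, model_params)
    return imps


def _rank_order(values: pd.Series) -> list[str]:
    """Feature names ordered by descending value, ties broken by name."""
    return sorted(values.index, key=lambda n: (-values[n], n))


def stability_check(importances: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Rank-stability report from per-fold importance vectors.

    A feature is *stable* when ordering features by the upper (right-tail)
    bound of their fold-wise confidence interval reproduces the ordering by
    mean importance at that feature's position.  With ``ci_level`` 0 the CI
    collapses to the mean and stability is exact rank agreement.
    """
    if importances.shape[0] < 2:
        raise ValueError("stability requires >= 2 folds")
    if not 0 <= ci_level < 1:
        raise ValueError("ci_level must be in [0, 1)")
    k = importances.shape[0]
    mean = importances.mean(axis=0)
    sd = importances.std(axis=0, ddof=1)
    half = stats.t.ppf(0.5 + ci_level / 2.0, k - 1) * sd / np.sqrt(k) if ci_level > 0 else 0.0
    upper = mean + half
    lower = mean - half
    by_mean = _rank_order(mean)
    by_upper = _rank_order(upper)
    pos_mean = {n: i for i, n in enumerate(by_mean)}
    pos_upper = {n: i for i, n in enumerate(by_upper)}
    report = pd.DataFrame(
        {
            "mean_importance": mean,
            "ci_low": lower,
            "ci_high": upper,
            "mean_rank": [pos_mean[n] + 1 for n in mean.index],
            "upper_rank": [pos_upper[n] + 1 for n in mean.index],
        }
    )
    report["stable"] = report["mean_rank"] == report["upper_rank"]
    return report


def progressive_elimination(
    X: FeatureTable | pd.DataFrame,
    y,
    k: int = 5,
    drop_fraction: float = 0.10,
    seed: int = 0,
    model_params: dict | None = None,
    ci_level: float = 0.95,
) -> EliminationTrace:
    """Progressively drop the lowest-importance features down to one.

    Each step records the retained set, per-fold validation micro-AUC,
    per-fold importances and the stability report; ``ceil(drop_fraction *
    m)`` features of lowest mean importance (ties broken by name) are
    removed per step.  All randomness derives from ``seed``.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    data = X.data if isinstance(X, FeatureTable) else X
    if data.shape[1] < 2:
        raise ValueError("need at least 2 features to eliminate")
    y = np.asarray(y)
    retained = list(data.columns)
    steps: list[EliminationStep] = []
    step_idx = 0
    while True:
        step_seed = int(
            np.random.SeedSequence([seed, step_idx]).generate_state(1)[0] % (2**31 - 1)
        )
        imps, aucs = _fold_run(data[retained], y, k, step_seed, model_params)
        stability = stability_check(imps, ci_level) if k >= 2 else pd.DataFrame()
        steps.append(
            EliminationStep(
                features=tuple(retained),
                fold_aucs=aucs,
                importances=imps,
                stability=stability,
            )
        )
        m = len(retained)
        if m == 1:
            break
        n_drop = min(int(np.ceil(drop_fraction * m)), m - 1)
        mean_imp = imps.mean(axis=0)
        by_weakness = sorted(retained, key=lambda n: (mean_imp[n], n))
        dropped = set(by_weakness[:n_drop])
        retained = [n for n in retained if n not in dropped]
        step_idx += 1
    return EliminationTrace(steps)


def select_optimal_n(
    trace: EliminationTrace, tolerance: float = 0.005
) -> tuple[int, tuple[str, ...]]:
    """Smallest retained-set size whose mean validation micro-AUC is within
    ``tolerance`` of the trace maximum; returns (N, that step's features)."""
    means = np.asarray(trace.mean_aucs())
    sizes = np.asarray(trace.sizes())
    finite = ~np.isnan(means)
    if not finite.any():
        step = trace.steps[-1]
        return step.n_features, step.features
    best = means[finite].max()
    ok = finite & (means >= best - tolerance)
    idx = int(np.flatnonzero(ok)[np.argmin(sizes[ok])])
    step = trace.steps[idx]
    return step.n_features, step.features
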