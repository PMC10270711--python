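"""One-vs-rest gradient-boosted classification and ROC evaluation.

The multiclass problem is decomposed into one binary dataset per class
(positive class = the group of interest, negative = everyone else); each
binary problem gets its own regularized gradient-boosted tree ensemble
(XGBoost) whose hyperparameters are tuned by Bayesian optimization of the
mean k-fold validation AUC.  Evaluation uses ROC curves: per-class AUC is
the Mann-Whitney probability (ties counted 1/2) and the micro-average AUC
is computed on the concatenation of all classes' (score, binary label)
pairs, which weighs samples and labels equally and is robust to class
imbalance.  ROC curves of two classifiers on the same subjects are compared
with a pooled-rank permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .bayesopt import HyperparamSpace, ParamRange, bayesian_optimize

__all__ = [
    "default_space",
    "make_classifier",
    "stratified_holdout_split",
    "binary_auc",
    "micro_average_auc",
    "roc_and_auc",
    "RocResult",
    "OvrModel",
    "fit_ovr_ensemble",
    "compare_rocs",
    "auc_confidence_interval",
]


def default_space() -> HyperparamSpace:
    """Search space over the boosted-ensemble hyperparameters: number of
    trees, depth, learning rate, minimum split loss, maximum leaves, and
    L1/L2 regularization weights."""
    return HyperparamSpace(
        {
            "n_estimators": ParamRange(20, 150, log=True, integer=True),
            "max_depth": ParamRange(2, 6, integer=True),
            "learning_rate": ParamRange(0.02, 0.4, log=True),
            "gamma": ParamRange(1e-4, 2.0, log=True),
            "max_leaves": ParamRange(4, 64, log=True, integer=True),
            "reg_alpha": ParamRange(1e-4, 10.0, log=True),
            "reg_lambda": ParamRange(1e-2, 10.0, log=True),
        }
    )


def make_classifier(params: dict | None = None, seed: int = 0) -> XGBClassifier:
    """XGBoost classifier with single-threaded, histogram-based defaults."""
    base = dict(
        n_estimators=60,
        max_depth=3,
        learning_rate=0.2,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )
    if params:
        base.update(params)
    return XGBClassifier(**base)


def gain_importances(model: XGBClassifier, feature_names: list[str]) -> np.ndarray:
    """Per-feature total-gain importances normalized to sum 1 (all-zero when
    no split was ever made)."""
    raw = model.get_booster().get_score(importance_type="total_gain")
    booster_names = model.get_booster().feature_names
    if booster_names is None:
        booster_names = [f"f{i}" for i in range(len(feature_names))]
    lookup = {name: raw.get(name, 0.0) for name in booster_names}
    vals = np.array([lookup.get(n, 0.0) for n in booster_names], dtype=float)
    total = vals.sum()
    return vals / total if total > 0 else vals


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def stratified_holdout_split(
    subject_ids, labels, test_fraction: float = 0.2, seed: int = 0
) -> tuple[list, list]:
    """Seeded stratified train/test partition of subject ids."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    subject_ids = list(subject_ids)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"classes with a single subject cannot be split: {small.tolist()}")
    train, test = train_test_split(
        subject_ids, test_size=test_fraction, stratify=labels, random_state=seed
    )
    return list(train), list(test)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def binary_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair-counting probability with ties as 1/2.

    ``nan`` when only one label value is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def micro_average_auc(score_matrix: np.ndarray, labels, classes=None) -> float:
    """Micro-average AUC: pool every class's (score, one-vs-rest label) pairs
    into one binary problem and take its AUC."""
    score_matrix = np.asarray(score_matrix, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    pooled_scores = []
    pooled_labels = []
    for k, cls in enumerate(classes):
        pooled_scores.append(score_matrix[:, k])
        pooled_labels.append(labels == cls)
    return binary_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))


@dataclass
class RocResult:
    """Per-class and pooled ROC evaluation."""

    classes: list
    per_class_auc: dict
    micro_auc: float
    macro_auc: float
    curves: dict
    micro_curve: tuple[np.ndarray, np.ndarray]
    notes: list[str] = field(default_factory=list)


def roc_and_auc(score_matrix: np.ndarray, labels, classes=None) -> RocResult:
    """ROC curves and AUCs for a matrix of one-vs-rest class scores.

    ``score_matrix`` is subjects x classes; ``labels`` the true class per
    subject.  Classes present with a single label value get ``nan`` AUC and
    a note rather than an error.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    if not np.all(np.isfinite(score_matrix)):
        raise ValueError("scores must be finite")
    labels = np.asarray(labels)
    if classes is None:
        classes = list(np.unique(labels))
    classes = list(classes)
    if score_matrix.shape != (labels.size, len(classes)):
        raise ValueError("score matrix must be subjects x classes")
    per_class = {}
    curves = {}
    notes = []
    for k, cls in enumerate(classes):
        y = labels == cls
        auc = binary_auc(score_matrix[:, k], y)
        per_class[cls] = auc
        if np.isnan(auc):
            notes.append(f"class {cls}: AUC undefined (single label value)")
            curves[cls] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        else:
            fpr, tpr, _ = roc_curve(y, score_matrix[:, k])
            curves[cls] = (fpr, tpr)
    valid = [v for v in per_class.values() if not np.isnan(v)]
    macro = float(np.mean(valid)) if valid else float("nan")
    pooled_scores = score_matrix.T.ravel()
    pooled_labels = np.concatenate([labels == cls for cls in classes])
    micro = binary_auc(pooled_scores, pooled_labels)
    if np.isnan(micro):
        micro_curve = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    else:
        fpr, tpr, _ = roc_curve(pooled_labels, pooled_scores)
        micro_curve = (fpr, tpr)
    return RocResult(
        classes=classes,
        per_class_auc=per_class,
        micro_auc=micro,
        macro_auc=macro,
        curves=curves,
        micro_curve=micro_curve,
        notes=notes,
    )


def auc_confidence_interval(fold_aucs, level: float = 0.95) -> tuple[float, float, float]:
    """t-interval (mean, low, high) over per-fold AUCs."""
    vals = np.asarray(fold_aucs, dtype=float)
    vals = vals[~np.isnan(vals)]
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, mean, mean
    half = stats.t.ppf(0.5 + level / 2.0, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
    return mean, mean - float(half), mean + float(half)


# ---------------------------------------------------------------------------
# one-vs-rest ensemble
# ---------------------------------------------------------------------------


@dataclass
class OvrModel:
    """One fitted binary gradient-boosted ensemble per class."""

    classes: list
    models: dict
    chosen_params: dict
    histories: dict
    k: int
    seed: int
    feature_names: list[str]

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous positive-class score per class, subjects x classes."""
        X = X[self.feature_names]
        out = np.column_stack(
            [self.models[cls].predict_proba(X)[:, 1] for cls in self.classes]
        )
        return out

    def importances(self) -> pd.DataFrame:
        rows = {
            cls: gain_importances(self.models[cls], self.feature_names)
            for cls in self.classes
        }
        return pd.DataFrame(rows, index=self.feature_names).T


def _cv_auc_objective(X, y_bin, k, seed, base_params):
    folds = list(
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(X, y_bin)
    )

    def objective(params: dict) -> float:
        aucs = []
        for tr, va in folds:
            model = make_classifier({**(base_params or {}), **params}, seed=seed)
            model.fit(X.iloc[tr], y_bin[tr])
            scores = model.predict_proba(X.iloc[va])[:, 1]
            aucs.append(binary_auc(scores, y_bin[va]))
        vals = [a for a in aucs if not np.isnan(a)]
        return float(np.mean(vals)) if vals else 0.5

    return objective


def fit_ovr_ensemble(
    X_train: pd.DataFrame,
    y_train,
    space: HyperparamSpace | None = None,
    k: int = 5,
    seed: int = 0,
    n_bo_iterations: int = 20,
    base_params: dict | None = None,
) -> OvrModel:
    """Fit one tuned binary booster per class (one-vs-rest).

    Hyperparameters for each class are chosen by Bayesian optimization of
    the mean k-fold validation AUC on the training partition, then the model
    is refit on the full training set with the chosen parameters.
    """
    y_train = np.asarray(y_train)
    classes = list(np.unique(y_train))
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    if space is None:
        space = default_space()
    models = {}
    chosen = {}
    histories = {}
    seeds = np.random.SeedSequence(seed).spawn(len(classes))
    for cls, ss in zip(classes, seeds):
        cls_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        y_bin = (y_train == cls).astype(int)
        objective = _cv_auc_objective(X_train, y_bin, k, cls_seed, base_params)
        best, history = bayesian_optimize(
            objective, space, n_iterations=n_bo_iterations, seed=cls_seed
        )
        model = make_classifier({**(base_params or {}), **best}, seed=cls_seed)
        model.fit(X_train, y_bin)
        models[cls] = model
        chosen[cls] = best
        histories[cls] = history
    return OvrModel(
        classes=classes,
        models=models,
        chosen_params=chosen,
        histories=histories,
        k=k,
        seed=seed,
        feature_names=list(X_train.columns),
    )


# ---------------------------------------------------------------------------
# ROC curve comparison
# ---------------------------------------------------------------------------


def _curve_difference(scores_a, scores_b, labels) -> float:
    """Integrated absolute difference between two ROC curves over the union
    grid of observed false-positive rates."""
    fa, ta, _ = roc_curve(labels, scores_a)
    fb, tb, _ = roc_curve(labels, scores_b)
    grid = np.union1d(fa, fb)
    ta_i = np.interp(grid, fa, ta)
    tb_i = np.interp(grid, fb, tb)
    return float(np.trapezoid(np.abs(ta_i - tb_i), grid))


def compare_rocs(
    scores_a,
    scores_b,
    labels,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for equality of two ROC curves on the same subjects.

    The statistic is the integrated absolute difference between the curves;
    the reference distribution permutes the pooled ranks of the two
    classifiers' test scores (rank both score vectors jointly, then swap the
    per-subject rank pair with probability 1/2).  Returns ``(p, observed)``
    with the add-one p-value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("both classifiers must score the same subjects")
    n = labels.size
    pooled = stats.rankdata(np.concatenate([scores_a, scores_b]))
    ra, rb = pooled[:n], pooled[n:]
    observed = _curve_difference(ra, rb, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        swap = rng.random(n) < 0.5
        pa = np.where(swap, rb, ra)
        pb = np.where(swap, ra, rb)
        if _curve_difference(pa, pb, labels) >= observed - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return p, observed
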