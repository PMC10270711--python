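"""Splits, AUC/ROC evaluation, Bayesian optimization, OvR ensembles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netclass.bayesopt import HyperparamSpace, ParamRange, bayesian_optimize
from netclass.classify import (
    binary_auc,
    compare_rocs,
    fit_ovr_ensemble,
    micro_average_auc,
    roc_and_auc,
    stratified_holdout_split,
)

from _oracles import pair_counting_auc


class TestHoldoutSplit:
    def test_balanced_counts(self):
        ids = [f"s{i}" for i in range(100)]
        y = ["a"] * 50 + ["b"] * 50
        train, test = stratified_holdout_split(ids, y, 0.2, seed=0)
        lab = dict(zip(ids, y))
        assert len(test) == 20
        assert sum(lab[s] == "a" for s in test) == 10

    def test_seed_contract_and_partition(self):
        ids = [f"s{i}" for i in range(40)]
        y = ["a"] * 20 + ["b"] * 20
        t1 = stratified_holdout_split(ids, y, 0.2, seed=1)
        t2 = stratified_holdout_split(ids, y, 0.2, seed=1)
        t3 = stratified_holdout_split(ids, y, 0.2, seed=2)
        assert t1 == t2 and t1 != t3
        train, test = t1
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="single"):
            stratified_holdout_split(["a", "b", "c"], ["x", "x", "y"], 0.3, 0)


class TestAuc:
    def test_separable_ties_and_pair_counting_example(self):
        assert binary_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert binary_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        assert binary_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(50):
            n = rng.integers(4, 30)
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert binary_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    @settings(max_examples=30, deadline=None)
    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_monotone_transform_invariance(self, kind):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        transform = {
            "exp": np.exp,
            "cube": lambda s: s**3,
            "affine": lambda s: 3.0 * s + 10,
        }[kind]
        assert binary_auc(transform(scores), labels) == pytest.approx(
            binary_auc(scores, labels), abs=1e-12
        )

    def test_micro_of_identical_single_problems_equals_single_auc(self, rng):
        scores = rng.standard_normal(30)
        labels = rng.integers(0, 2, 30)
        single = binary_auc(scores, labels)
        stacked = np.tile(scores[:, None], (1, 3))
        # three identical one-vs-rest problems with the same binary labels
        pooled = binary_auc(np.tile(scores, 3), np.tile(labels, 3))
        assert pooled == pytest.approx(single, abs=1e-12)
        del stacked

    def test_roc_and_auc_structure(self, rng):
        n = 60
        y = rng.choice(list("abc"), n)
        scores = rng.standard_normal((n, 3))
        res = roc_and_auc(scores, y, classes=["a", "b", "c"])
        for k, cls in enumerate(["a", "b", "c"]):
            assert res.per_class_auc[cls] == pytest.approx(
                pair_counting_auc(scores[:, k], y == cls), abs=1e-12
            )
        pooled = np.concatenate([scores[:, k] for k in range(3)])
        pooled_y = np.concatenate([y == c for c in "abc"])
        assert res.micro_auc == pytest.approx(pair_counting_auc(pooled, pooled_y), abs=1e-12)
        fpr, tpr = res.micro_curve
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_label_class_reported_not_raised(self, rng):
        y = np.array(["a"] * 5 + ["b"] * 5)
        scores = rng.standard_normal((10, 3))
        res = roc_and_auc(scores, y, classes=["a", "b", "c"])
        assert np.isnan(res.per_class_auc["c"])
        assert any("c" in note for note in res.notes)


class TestBayesianOptimize:
    def space2d(self):
        return HyperparamSpace({"x": ParamRange(0, 1), "y": ParamRange(0, 1)})

    def test_incumbent_monotone_and_single_iteration(self):
        obj = lambda p: -((p["x"] - 0.4) ** 2) - (p["y"] - 0.6) ** 2
        best, history = bayesian_optimize(obj, self.space2d(), n_iterations=15, seed=0)
        scores = [h["best_so_far"] for h in history if h["score"] is not None]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))
        best1, history1 = bayesian_optimize(obj, self.space2d(), n_iterations=1, seed=0)
        assert len(history1) == 1 and best1 == history1[0]["params"]

    def test_failed_evaluations_recorded_and_search_continues(self):
        calls = []

        def flaky(p):
            calls.append(p)
            if len(calls) % 3 == 0:
                raise RuntimeError("boom")
            return -((p["x"] - 0.5) ** 2)

        best, history = bayesian_optimize(flaky, self.space2d(), n_iterations=12, seed=1)
        failed = [h for h in history if h["score"] is None]
        assert len(failed) >= 1 and all("error" in h for h in failed)
        assert best is not None

    def test_log_and_integer_ranges(self):
        space = HyperparamSpace(
            {"n": ParamRange(8, 256, log=True, integer=True), "lr": ParamRange(1e-3, 1.0, log=True)}
        )
        best, history = bayesian_optimize(
            lambda p: -abs(np.log(p["lr"])), space, n_iterations=5, seed=0
        )
        for h in history:
            assert isinstance(h["params"]["n"], int) and 8 <= h["params"]["n"] <= 256
            assert 1e-3 <= h["params"]["lr"] <= 1.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            ParamRange(1.0, 0.5)
        with pytest.raises(ValueError, match="positive"):
            ParamRange(0.0, 1.0, log=True)


def toy_features(rng, n_per, n_classes=2, n_features=5, informative_shift=3.0):
    X, y = [], []
    for c in range(n_classes):
        block = rng.standard_normal((n_per, n_features))
        block[:, 0] += informative_shift * c
        X.append(block)
        y += [f"g{c}"] * n_per
    data = pd.DataFrame(np.vstack(X), columns=[f"f{i}" for i in range(n_features)])
    return data, np.array(y)


class TestOvrEnsemble:
    def test_separable_two_class_reaches_perfect_training_auc(self, rng):
        X, y = toy_features(rng, 30, informative_shift=8.0)
        model = fit_ovr_ensemble(X, y, k=3, seed=0, n_bo_iterations=2)
        scores = model.predict_scores(X)
        assert binary_auc(scores[:, 1], y == "g1") == 1.0

    def test_six_classes_yield_six_binary_models(self, rng):
        X, y = toy_features(rng, 12, n_classes=6)
        model = fit_ovr_ensemble(X, y, k=3, seed=0, n_bo_iterations=1)
        assert len(model.models) == 6
        assert model.predict_scores(X).shape == (72, 6)

    def test_single_class_input_rejected(self, rng):
        X, _ = toy_features(rng, 10)
        with pytest.raises(ValueError, match="two classes"):
            fit_ovr_ensemble(X, np.array(["g0"] * 20), k=3, seed=0)

    def test_label_permuted_training_gives_chance_validation_auc(self, rng):
        from netclass.classify import _cv_auc_objective

        aucs = []
        for seed in range(6):
            local = np.random.default_rng(seed)
            X, y = toy_features(local, 40, informative_shift=0.0)
            y_bin = (y == "g1").astype(int)
            local.shuffle(y_bin)
            obj = _cv_auc_objective(X, y_bin, 5, seed, None)
            aucs.append(obj({"n_estimators": 40, "max_depth": 3}))
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestCompareRocs:
    def test_identical_classifiers_give_p_one(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        p, stat = compare_rocs(scores, scores.copy(), labels, n_permutations=100, seed=0)
        assert p == 1.0 and stat == 0.0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="same subjects"):
            compare_rocs(np.zeros(5), np.zeros(6), np.zeros(5), 10, 0)

    def test_perfect_vs_random_detected(self, rng):
        hits = 0
        for seed in range(5):
            local = np.random.default_rng(seed)
            labels = np.array([0, 1] * 50)
            perfect = labels + 0.01 * local.standard_normal(100)
            noise = local.standard_normal(100)
            p, _ = compare_rocs(perfect, noise, labels, n_permutations=200, seed=seed)
            hits += p < 0.05
        assert hits >= 4
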