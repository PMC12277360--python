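"""SMOTE, rank AUC, one-vs-rest type models and the age-group model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay

from kscope import models


class TestSmote:
    def test_two_points_on_segment(self, rng):
        x = np.array([[0.0, 0.0], [2.0, 2.0]])
        synth = models.smote(x, target_count=10, seed=1)
        assert len(synth) == 8
        # every synthetic lies on the segment y = x within [0, 2]
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert (synth >= 0).all() and (synth <= 2).all()

    def test_no_oversampling_needed(self):
        x = np.ones((5, 3))
        assert len(models.smote(x, target_count=5, seed=0)) == 0
        assert len(models.smote(x, target_count=3, seed=0)) == 0

    def test_convex_hull_membership(self, rng):
        """Synthetics stay inside the minority convex hull (2-D toy)."""
        x = rng.normal(size=(12, 2))
        synth = models.smote(x, target_count=60, seed=2)
        hull = Delaunay(x)
        assert (hull.find_simplex(synth) >= 0).all()
        for j in range(2):
            assert (synth[:, j] >= x[:, j].min() - 1e-12).all()
            assert (synth[:, j] <= x[:, j].max() + 1e-12).all()

    def test_singleton_duplicates_with_warning(self):
        with pytest.warns(UserWarning):
            synth = models.smote(np.array([[1.0, 2.0]]), target_count=4, seed=0)
        assert (synth == [1.0, 2.0]).all() and len(synth) == 3

    def test_deterministic(self, rng):
        x = rng.normal(size=(8, 3))
        a = models.smote(x, target_count=20, seed=7)
        b = models.smote(x, target_count=20, seed=7)
        assert np.array_equal(a, b)


class TestRocAuc:
    def test_worked_examples(self):
        assert models.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75
        assert models.roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert models.roc_auc([0.5] * 6, [0, 1] * 3) == 0.5  # all ties

    def test_brute_force_equivalence(self, rng):
        """Rank AUC equals pairwise comparison with tie half-credit."""
        for _ in range(10):
            n = int(rng.integers(5, 50))
            scores = rng.choice([0.1, 0.2, 0.3, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean(
                [1.0 if p > q else (0.5 if p == q else 0.0)
                 for p, q in itertools.product(pos, neg)]
            )
            assert models.roc_auc(scores, labels) == pytest.approx(brute)

    def test_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        assert models.roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_single_class_flagged(self):
        with pytest.raises(ValueError):
            models.roc_auc([0.1, 0.2], [1, 1])

    def test_micro_macro(self):
        per_class = {
            "a": (np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])),
            "b": (np.array([0.2, 0.7, 0.6]), np.array([0, 1, 1])),
        }
        micro, macro = models.micro_macro(per_class)
        assert macro == pytest.approx(
            (models.roc_auc(*per_class["a"]) + models.roc_auc(*per_class["b"])) / 2
        )
        pooled_scores = np.r_[per_class["a"][0], per_class["b"][0]]
        pooled_labels = np.r_[per_class["a"][1], per_class["b"][1]]
        assert micro == pytest.approx(models.roc_auc(pooled_scores, pooled_labels))


def make_typed_cohort(rng, n=240, signal=4.0):
    """Feature table with a planted genus signature per type."""
    types = np.array(["HH", "HL", "LH", "LL"])[rng.integers(0, 4, n)]
    groups = np.array(["Young", "Old"])[rng.integers(0, 2, n)]
    X = rng.normal(size=(n, 6))
    for j, t in enumerate(["HH", "HL", "LH", "LL"]):
        X[types == t, j] += signal
    idx = [f"s{i}" for i in range(n)]
    features = pd.DataFrame(X, index=idx, columns=[f"G{j}" for j in range(6)])
    labels = pd.DataFrame({"aging_group": groups, "final_type": types}, index=idx)
    return features, labels


class TestTrainTypeModels:
    def test_planted_signal_high_auc(self, rng):
        features, labels = make_typed_cohort(rng, n=400, signal=5.0)
        results = models.train_type_models(features, labels,
                                           models.ModelSpec(seed=0))
        assert len(results) == 8     # 2 groups x 4 types
        for r in results:
            assert r.test_auc > 0.9
        assert np.mean([r.test_auc for r in results]) > 0.95

    def test_shuffled_labels_near_chance(self, rng):
        features, labels = make_typed_cohort(rng, signal=0.0)
        aucs = []
        for seed in range(4):
            res = models.train_type_models(features, labels,
                                           models.ModelSpec(seed=seed))
            aucs.extend(r.test_auc for r in res)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_stratified_split_ratio_within_one(self, rng):
        features, labels = make_typed_cohort(rng)
        y = (labels["final_type"] == "HH").astype(int)
        X_tr, X_te, y_tr, y_te = models.stratified_split(
            features, y, models.ModelSpec(seed=0)
        )
        expect = y.mean() * len(y_tr)
        assert abs(y_tr.sum() - expect) <= 1

    def test_tiny_type_skipped(self, rng):
        features, labels = make_typed_cohort(rng, n=60)
        labels.loc[labels["final_type"] == "LL", "final_type"] = "LH"
        labels.iloc[:3, labels.columns.get_loc("final_type")] = "LL"
        with pytest.warns(UserWarning, match="LL"):
            results = models.train_type_models(features, labels,
                                               models.ModelSpec(seed=0))
        assert all(r.type_label != "LL" for r in results)


class TestImportanceHeatmap:
    def test_planted_genus_peaks_and_rows_standardized(self, rng):
        features, labels = make_typed_cohort(rng)
        results = models.train_type_models(features, labels,
                                           models.ModelSpec(seed=0))
        z = models.feature_importance_heatmap(results)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        nonconst = z.std(axis=1, ddof=0) > 0
        assert np.allclose(z.std(axis=1, ddof=0)[nonconst], 1.0)
        # G0 (the HH signature) peaks in HH columns
        hh_cols = [c for c in z.columns if c.endswith(":HH")]
        assert z.loc["G0", hh_cols].mean() > 0


class TestAgeModel:
    def test_planted_age_signal(self, rng):
        n = 300
        decades = np.array(["10s", "30s", "50s"])[rng.integers(0, 3, n)]
        offset = {"10s": 0.0, "30s": 2.0, "50s": 4.0}
        X = rng.normal(size=(n, 5))
        X[:, 0] += np.vectorize(offset.get)(decades)
        features = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                                columns=[f"f{j}" for j in range(5)])
        report = models.evaluate_age_model(
            features, pd.Series(decades, index=features.index),
            models.ModelSpec(seed=0),
        )
        assert report.micro_auc > 0.8
        assert set(report.per_class) == {"10s", "30s", "50s"}
        assert report.macro_auc == pytest.approx(
            np.mean(list(report.per_class.values()))
        )

    def test_shuffled_near_chance(self, rng):
        n = 300
        X = rng.normal(size=(n, 5))
        features = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                                columns=[f"f{j}" for j in range(5)])
        decades = pd.Series(np.array(["a", "b"])[rng.integers(0, 2, n)],
                            index=features.index)
        report = models.evaluate_age_model(features, decades,
                                           models.ModelSpec(seed=1))
        assert abs(report.micro_auc - 0.5) < 0.15
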