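"""Classifier benchmarking: LOOCV mechanics, cluster mapping, grid
search and under-sampling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gaitpark as gp
from gaitpark.classify import SUPERVISED_MODELS, UNSUPERVISED_MODELS, _standardize
from gaitpark.types import ValidationError
from conftest import make_feature_table


def separable_table(n_per_class: int = 20, d: int = 5, dist_sd: float = 6.0, seed: int = 0):
    """Two Gaussian classes at mean distance ``dist_sd`` standard
    deviations, the shift split over the first two features (near
    axis-aligned, so single trees can also express the boundary); the
    remaining d-2 features are exchangeable noise."""
    rng = np.random.default_rng(seed)
    shift = dist_sd / np.sqrt(2)
    rows = []
    for label, s in (("healthy", 0.0), ("PD", 1.0)):
        for i in range(n_per_class):
            row = {"record_id": f"{label}{i}", "subject_id": f"{label}{i}", "label": label}
            row["f1"] = rng.normal(s * shift, 1.0)
            row["f2"] = rng.normal(s * shift, 1.0)
            row.update({f"f{j+1}": rng.normal(0.0, 1.0) for j in range(2, d)})
            rows.append(row)
    return gp.FeatureTable(pd.DataFrame(rows))


ALL_SPECS = [
    gp.ClassifierSpec("knn", params={"k": 3}),
    gp.ClassifierSpec("cart"),
    gp.ClassifierSpec("rf", params={"n_trees": 50}),
    gp.ClassifierSpec("nb"),
    gp.ClassifierSpec("svm", params={"kernel": "poly", "degree": 3}),
    gp.ClassifierSpec("kmeans"),
    gp.ClassifierSpec("gmm", params={"covariance": "full"}),
]


class TestLOOCV:
    def test_fold_count_equals_record_count(self):
        table = separable_table(n_per_class=8)
        preds = gp.loocv_predict(table, gp.ClassifierSpec("nb"))
        assert np.unique(preds.fold).size == 16
        assert len(preds.record_ids) == 16

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.name)
    def test_separable_benchmark(self, spec):
        """Well-separated Gaussians: every supervised model reaches
        >= 95% LOOCV accuracy; unsupervised also succeed here."""
        table = separable_table(n_per_class=20, seed=1)
        preds = gp.loocv_predict(table, spec)
        floor = 95.0 if spec.is_supervised else 85.0
        assert preds.accuracy >= floor

    def test_supervised_beats_unsupervised_on_benchmark(self):
        table = separable_table(n_per_class=20, dist_sd=3.0, seed=2)
        sup = max(gp.loocv_predict(table, gp.ClassifierSpec(m, params={"k": 3} if m == "knn" else {})).accuracy
                  for m in ("knn", "svm", "rf"))
        unsup = max(gp.loocv_predict(table, gp.ClassifierSpec(m)).accuracy
                    for m in UNSUPERVISED_MODELS)
        assert sup >= unsup

    def test_label_permutation_chance_band(self):
        """Shuffled labels: accuracy stays in the permutation band."""
        accs = []
        for seed in range(10):
            table = separable_table(n_per_class=15, seed=seed)
            rng = np.random.default_rng(seed)
            df = table.data.copy()
            df["label"] = rng.permutation(df["label"].to_numpy())
            try:
                preds = gp.loocv_predict(gp.FeatureTable(df), gp.ClassifierSpec("nb"))
            except ValidationError:
                continue  # a fold collapsed to one class
            accs.append(preds.accuracy)
        assert 35.0 <= np.mean(accs) <= 65.0

    def test_record_order_invariance_deterministic_models(self):
        table = separable_table(n_per_class=10, dist_sd=2.0, seed=3)
        shuffled = gp.FeatureTable(
            table.data.sample(frac=1.0, random_state=7).reset_index(drop=True))
        for name, params in (("knn", {"k": 3}), ("nb", {}), ("svm", {"kernel": "linear"})):
            a = gp.loocv_predict(table, gp.ClassifierSpec(name, params=params))
            b = gp.loocv_predict(shuffled, gp.ClassifierSpec(name, params=params))
            da = dict(zip(a.record_ids, a.y_pred))
            db = dict(zip(b.record_ids, b.y_pred))
            assert da == db

    def test_fold_collapse_error_names_fold(self):
        df = separable_table(n_per_class=2).data  # leaving one out can't collapse... force it
        df = df[df["label"].ne("PD") | (df["record_id"] == "PD0")].reset_index(drop=True)
        with pytest.raises(ValidationError, match="fold"):
            gp.loocv_predict(gp.FeatureTable(df), gp.ClassifierSpec("nb"))

    def test_standardization_is_fold_local(self):
        """Fold-local vs global statistics produce different inputs by
        construction: the held-out record shifts the global mean."""
        table = separable_table(n_per_class=5, seed=4)
        X = table.X()
        test = np.zeros(len(X), dtype=bool)
        test[0] = True
        Xtr_local, _ = _standardize(X[~test], X[test])
        mu_global = X.mean(axis=0)
        sd_global = X.std(axis=0)
        Xtr_global = (X[~test] - mu_global) / sd_global
        assert not np.allclose(Xtr_local, Xtr_global)

    def test_subject_grouping_holds_out_all_records_of_subject(self):
        table = separable_table(n_per_class=6, seed=5)
        df = table.data.copy()
        df["subject_id"] = [f"s{i // 2}" for i in range(len(df))]  # 2 records/subject
        preds = gp.loocv_predict(gp.FeatureTable(df), gp.ClassifierSpec("nb"),
                                 grouping="subject")
        assert np.unique(preds.fold).size == len(df) // 2


class TestMapClusters:
    def test_identity_mapping(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        assignments = np.array([0] * 5 + [1] * 5)
        m = gp.map_clusters(assignments, labels)
        assert m[0] == "a" and m[1] == "b"

    def test_inverted_mapping(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        assignments = np.array([1] * 5 + [0] * 5)
        m = gp.map_clusters(assignments, labels)
        assert m[0] == "b" and m[1] == "a"

    def test_random_assignment_accuracy_at_least_half(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.choice(["a", "b"], 30)
            assignments = rng.integers(0, 2, 30)
            m = gp.map_clusters(assignments, labels)
            acc = np.mean([m[int(c)] == l for c, l in zip(assignments, labels)])
            assert acc >= 0.5


class TestGridSearch:
    def test_single_point_grid_identity(self):
        table = separable_table(n_per_class=8)
        spec = gp.ClassifierSpec("knn", grid={"k": [3]})
        best, acc = gp.grid_search(table, spec)
        assert best.params["k"] == 3 and acc > 90

    def test_simplest_model_wins_ties(self):
        table = separable_table(n_per_class=10, seed=6)
        best, _ = gp.grid_search(table, gp.ClassifierSpec("knn", grid={"k": list(range(2, 11))}))
        # perfectly separable: every K is 100% accurate; smallest K kept
        assert best.params["k"] == 2

    def test_rf_grid_deterministic(self):
        table = separable_table(n_per_class=8, dist_sd=2.0, seed=7)
        grid = {"n_trees": [10, 30, 50]}
        a, _ = gp.grid_search(table, gp.ClassifierSpec("rf", grid=dict(grid), seed=5))
        b, _ = gp.grid_search(table, gp.ClassifierSpec("rf", grid=dict(grid), seed=5))
        assert a.params == b.params

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            gp.grid_search(separable_table(4), gp.ClassifierSpec("knn"))


class TestUnderSample:
    def _table(self, n_a: int, n_b: int, label_a="HD", label_b="PD"):
        rows = []
        for label, n in ((label_a, n_a), (label_b, n_b)):
            for i in range(n):
                rows.append({"record_id": f"{label}{i}", "subject_id": f"{label}{i}",
                             "label": label, "f1": float(i)})
        return gp.FeatureTable(pd.DataFrame(rows))

    def test_20_hd_vs_15_pd(self):
        out = gp.under_sample(self._table(20, 15), seed=0)
        assert out.data["label"].value_counts().to_dict() == {"HD": 15, "PD": 15}

    def test_13_als_vs_15_pd(self):
        out = gp.under_sample(self._table(13, 15, label_a="ALS"), seed=0)
        assert out.data["label"].value_counts().to_dict() == {"ALS": 13, "PD": 13}

    def test_balanced_input_preserves_rows(self):
        table = self._table(10, 10)
        out = gp.under_sample(table, seed=1)
        assert sorted(out.data["record_id"]) == sorted(table.data["record_id"])

    def test_deterministic_given_seed(self):
        table = self._table(25, 10)
        a = gp.under_sample(table, seed=3)
        b = gp.under_sample(table, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)
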