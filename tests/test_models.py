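"""Supervised classifiers: shared contract, NB oracle, nested CV."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cytofingerprint as cf

REDUCED = {
    "GB": {"n_trees": 20, "max_depth": 3},
    "DRF": {"n_trees": 50},
    "NB": {},
    "DL": {"hidden": (100, 50, 25), "epochs": 5},
}


def toy_dataset(X, y):
    X = np.asarray(X, dtype=float)
    return cf.LabeledDataset(
        X=X,
        labels=np.asarray(y, dtype=object),
        provenance=pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(X))], "replicate": 1,
             "timepoint": 0, "chunk_index": range(len(X))}
        ),
        chunk_size=max(1, X.shape[1] // 3),
    )


def blobs(n_per_class=30, centers=((0, 0), (8, 8), (0, 8), (8, 0)), seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, c in enumerate(centers):
        X.append(rng.normal(loc=c, scale=0.5, size=(n_per_class, len(c))))
        y += [f"C{k}"] * n_per_class
    return toy_dataset(np.vstack(X), y)


@pytest.mark.parametrize("algo", cf.ALGORITHMS)
class TestSharedContract:
    def test_separable_classes_learned(self, algo):
        ds = blobs()
        clf = cf.train(cf.ModelSpec(algo, REDUCED[algo], seed=0), ds)
        overall, per_class = cf.accuracy(clf, ds)
        assert overall >= 0.99
        assert all(v >= 0.95 for v in per_class.values())

    def test_probability_rows_on_simplex(self, algo):
        ds = blobs()
        clf = cf.train(cf.ModelSpec(algo, REDUCED[algo], seed=0), ds)
        probs = clf.predict_proba(ds)
        assert probs.shape == (len(ds), 4)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_fixed_seed_identical_predictions(self, algo):
        ds = blobs(seed=3)
        p = [
            cf.train(cf.ModelSpec(algo, REDUCED[algo], seed=7), ds).predict_proba(ds)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(p[0], p[1])

    def test_single_label_training_rejected(self, algo):
        ds = toy_dataset(np.random.default_rng(0).normal(size=(10, 2)), ["A"] * 10)
        with pytest.raises(ValueError, match="2 labels"):
            cf.train(cf.ModelSpec(algo, REDUCED[algo]), ds)

    def test_dimension_mismatch_rejected(self, algo):
        ds = blobs()
        clf = cf.train(cf.ModelSpec(algo, REDUCED[algo], seed=0), ds)
        with pytest.raises(ValueError, match="expected"):
            clf.predict_proba(np.zeros((3, 7)))

    def test_save_load_round_trip(self, algo, tmp_path):
        ds = blobs(seed=5)
        clf = cf.train(cf.ModelSpec(algo, REDUCED[algo], seed=1), ds)
        path = clf.save(tmp_path / f"{algo}.pkl")
        back = cf.TrainedClassifier.load(path)
        np.testing.assert_array_equal(back.predict_proba(ds), clf.predict_proba(ds))


class TestNaiveBayes:
    def test_posterior_matches_brute_force_bayes(self):
        """Gaussian NB posteriors equal a by-hand Bayes computation with the
        same per-class means, variances and variance floor."""
        X = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.5], [6.0, 7.0], [7.0, 6.0], [6.5, 6.5]])
        y = ["a", "a", "a", "b", "b", "b"]
        ds = toy_dataset(X, y)
        clf = cf.train(cf.ModelSpec("NB"), ds)
        eps = 1e-9 * X.var(axis=0).max()  # the variance floor
        query = np.array([[2.0, 2.0], [5.0, 5.0], [1.0, 7.0]])
        for q, probs in zip(query, clf.predict_proba(query)):
            log_post = []
            for label in ("a", "b"):
                Xc = X[np.asarray(y) == label]
                mu, var = Xc.mean(axis=0), Xc.var(axis=0) + eps
                ll = np.sum(-0.5 * np.log(2 * np.pi * var) - (q - mu) ** 2 / (2 * var))
                log_post.append(np.log(0.5) + ll)
            log_post = np.array(log_post)
            expected = np.exp(log_post - log_post.max())
            expected /= expected.sum()
            np.testing.assert_allclose(probs, expected, rtol=1e-9, atol=1e-12)

    def test_zero_within_class_variance_handled(self):
        X = np.array([[1.0, 5.0], [1.0, 5.0], [2.0, 5.0], [2.0, 5.0]])
        ds = toy_dataset(X, ["a", "a", "b", "b"])
        clf = cf.train(cf.ModelSpec("NB"), ds)
        probs = clf.predict_proba(ds)
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestAccuracy:
    def test_hand_built_confusion_seven_of_ten(self):
        class Fixed:
            def predict_proba(self, X):
                # argmax class per row: first 7 correct (A,A,A,A,B,B,B), last 3 wrong
                rows = [[0.9, 0.1]] * 4 + [[0.1, 0.9]] * 3 + [[0.1, 0.9]] * 3
                return np.array(rows[: len(X)])

        clf = cf.TrainedClassifier(
            spec=cf.ModelSpec("NB"), classes_=np.array(["A", "B"]),
            backend=Fixed(), n_features=2,
        )
        truth = ["A"] * 4 + ["B"] * 3 + ["A"] * 3  # last 3 misclassified as B
        test = toy_dataset(np.zeros((10, 2)), truth)
        overall, per_class = cf.accuracy(clf, test)
        assert overall == pytest.approx(0.7)
        assert per_class == {"A": pytest.approx(4 / 7), "B": pytest.approx(1.0)}

    def test_unseen_test_label_counted_misclassified(self):
        ds = blobs(n_per_class=10, centers=((0, 0), (8, 8)))
        clf = cf.train(cf.ModelSpec("NB"), ds)
        test = toy_dataset([[0.0, 0.0], [20.0, -5.0]], ["C0", "Z"])
        overall, per_class = cf.accuracy(clf, test)
        assert per_class["Z"] == 0.0
        assert overall == pytest.approx(0.5)

    def test_per_class_threshold_variant(self):
        class Fixed:
            def predict_proba(self, X):
                return np.tile([0.6, 0.4], (len(X), 1))

        clf = cf.TrainedClassifier(
            spec=cf.ModelSpec("NB"), classes_=np.array(["A", "B"]),
            backend=Fixed(), n_features=2,
        )
        test = toy_dataset(np.zeros((4, 2)), ["A", "A", "B", "B"])
        _, per_class = cf.accuracy(clf, test, per_class_thresholds={"A": 0.5, "B": 0.5})
        assert per_class == {"A": 1.0, "B": 0.0}


class TestNestedCV:
    def test_single_point_grid_returns_it_with_outer_folds(self):
        ds = blobs(n_per_class=20, seed=1)
        spec, cv = cf.nested_cv_grid_search("NB", [{}], ds, outer_folds=4, inner_folds=3, seed=0)
        assert spec.algorithm == "NB"
        assert len(cv.fold_accuracies) == 4
        assert 0.0 <= cv.mean <= 1.0

    def test_xor_data_selects_deeper_trees(self):
        """Depth-1 boosted stumps are additive and cannot represent XOR;
        the grid search must select the deeper setting."""
        rng = np.random.default_rng(0)
        n = 60
        x = rng.integers(0, 2, size=(n, 2)).astype(float)
        y = np.where(x[:, 0] != x[:, 1], "pos", "neg")
        X = x + rng.normal(scale=0.05, size=x.shape)
        ds = toy_dataset(X, y)
        grid = {"max_depth": [1, 5], "n_trees": [30]}
        spec, _ = cf.nested_cv_grid_search("GB", grid, ds, seed=0)
        assert spec.hyperparameters["max_depth"] == 5

    def test_outer_folds_disjoint_and_stratified(self):
        from sklearn.model_selection import StratifiedKFold

        ds = blobs(n_per_class=16, seed=2)
        y = ds.labels.astype(str)
        outer = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        seen = np.zeros(len(ds), dtype=int)
        for tr, te in outer.split(ds.X, y):
            assert not set(tr) & set(te)
            seen[te] += 1
            # stratification: each fold holds n_per_class/4 of each label
            counts = pd.Series(y[te]).value_counts()
            assert set(counts) == {4}
        assert (seen == 1).all()

    def test_empty_grid_rejected(self):
        ds = blobs(n_per_class=10)
        with pytest.raises(ValueError, match="empty"):
            cf.nested_cv_grid_search("NB", [], ds)

    def test_label_smaller_than_outer_folds_rejected(self):
        ds = blobs(n_per_class=3)
        with pytest.raises(ValueError, match="fewer"):
            cf.nested_cv_grid_search("NB", [{}], ds, outer_folds=4)


class TestKFoldStability:
    def test_separable_data_high_accuracy_on_every_fold(self):
        ds = blobs(n_per_class=25, seed=4)
        cv = cf.kfold_stability(cf.ModelSpec("DRF", REDUCED["DRF"], seed=0), ds, k=5, seed=0)
        assert len(cv.fold_accuracies) == 5
        assert all(a >= 0.95 for a in cv.fold_accuracies)
        assert cv.mean == pytest.approx(np.mean(cv.fold_accuracies))

    def test_label_smaller_than_k_rejected(self):
        ds = blobs(n_per_class=3)
        with pytest.raises(ValueError, match="fewer than k"):
            cf.kfold_stability(cf.ModelSpec("NB"), ds, k=5)


def test_unknown_hyperparameter_rejected():
    with pytest.raises(ValueError, match="unknown hyperparameter"):
        cf.ModelSpec("GB", {"n_tres": 10}).resolved()


def test_default_hyperparameters_match_printed_configuration():
    assert cf.ModelSpec("GB").resolved()["n_trees"] == 200
    assert cf.ModelSpec("GB").resolved()["max_depth"] == 5
    assert cf.ModelSpec("DRF").resolved()["max_depth"] == 20
    dl = cf.ModelSpec("DL").resolved()
    assert dl["hidden"] == (2000, 1000, 500)
    assert dl["hidden_dropout"] == (0.2, 0.2, 0.1)
    assert dl["input_dropout"] == 0.1
    assert dl["epochs"] == 10
    assert dl["l1"] == dl["l2"] == 1e-5
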