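"""ROC/AUC, confusion matrices, probability summaries, Gedeon importance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytofingerprint as cf
from cytofingerprint.evaluation import gedeon_scores


def pair_count_auc(scores, truth, positive):
    """Mann-Whitney oracle: fraction of (pos, neg) pairs ranked correctly,
    ties counted one half."""
    pos = [s for s, t in zip(scores, truth) if t == positive]
    neg = [s for s, t in zip(scores, truth) if t != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def two_col(scores_pos):
    s = np.asarray(scores_pos, dtype=float)
    return np.column_stack([s, 1 - s])


class TestOneVsAllROC:
    def test_perfect_ranking_gives_auc_one(self):
        scores = two_col([0.9, 0.8, 0.2, 0.1])
        r = cf.one_vs_all_roc(scores, ["p", "p", "n", "n"], "p", ["p", "n"])
        assert r.auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        scores = two_col([0.5] * 6)
        r = cf.one_vs_all_roc(scores, ["p", "n"] * 3, "p", ["p", "n"])
        assert r.auc == pytest.approx(0.5)

    def test_hand_listed_pairs_match_pair_count(self):
        scores_pos = [0.9, 0.6, 0.6, 0.4, 0.3, 0.1]
        truth = ["p", "n", "p", "p", "n", "n"]
        r = cf.one_vs_all_roc(two_col(scores_pos), truth, "p", ["p", "n"])
        assert r.auc == pytest.approx(pair_count_auc(scores_pos, truth, "p"), abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40),
        st.data(),
    )
    def test_trapezoidal_auc_equals_mann_whitney(self, scores_pos, data):
        n = len(scores_pos)
        truth = data.draw(
            st.lists(st.sampled_from(["p", "n"]), min_size=n, max_size=n)
        )
        if "p" not in truth or "n" not in truth:
            truth = ["p"] + ["n"] * (n - 1)
        # round to a coarse grid so ties actually occur
        scores_pos = [round(s, 1) for s in scores_pos]
        r = cf.one_vs_all_roc(two_col(scores_pos), truth, "p", ["p", "n"])
        assert r.auc == pytest.approx(pair_count_auc(scores_pos, truth, "p"), abs=1e-12)

    def test_roc_curve_monotone_between_corners(self):
        rng = np.random.default_rng(0)
        scores_pos = rng.random(50)
        truth = ["p" if rng.random() < 0.5 else "n" for _ in range(50)]
        if "p" not in truth:
            truth[0] = "p"
        if "n" not in truth:
            truth[1] = "n"
        r = cf.one_vs_all_roc(two_col(scores_pos), truth, "p", ["p", "n"])
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert 0.0 <= r.auc <= 1.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="positives and negatives"):
            cf.one_vs_all_roc(two_col([0.5, 0.6]), ["p", "p"], "p", ["p", "n"])

    def test_label_independent_scores_near_half_for_four_classes(self):
        """For balanced 4-class truth and label-independent scores, each
        one-vs-all AUC sits within 0.5 +/- 3 SE."""
        rng = np.random.default_rng(7)
        n = 400
        classes = ["A", "B", "C", "D"]
        truth = np.repeat(classes, n // 4)
        scores = rng.random((n, 4))
        scores /= scores.sum(axis=1, keepdims=True)
        n_pos, n_neg = n // 4, 3 * n // 4
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        for c in classes:
            r = cf.one_vs_all_roc(scores, truth, c, classes)
            assert abs(r.auc - 0.5) < 3 * se


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        truth = ["A", "B", "C", "A"]
        m = cf.confusion_matrix(truth, truth)
        assert (np.asarray(m) == np.diag([2, 1, 1])).all()

    def test_single_swap_off_diagonal(self):
        m = cf.confusion_matrix(["A", "B", "B", "B"], ["A", "A", "B", "B"])
        assert m.loc["A", "B"] == 1
        assert m.loc["A", "A"] == 1
        assert m.to_numpy().sum() == 4

    def test_row_sums_equal_support_and_recall_matches_accuracy(self, split_4class):
        train, test = split_4class
        clf = cf.train(cf.ModelSpec("NB"), train)
        pred = clf.predict(test)
        m = cf.confusion_matrix(pred, test.labels)
        assert m.to_numpy().sum() == len(test)
        _, per_class = cf.accuracy(clf, test)
        for label in m.index:
            support = m.loc[label].sum()
            assert support == np.sum(test.labels == label)
            assert m.loc[label, label] / support == pytest.approx(per_class[label])


class TestClassProbabilitySummary:
    def test_perfect_predictor_medians(self):
        scores = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        df = cf.class_probability_summary(scores, ["A", "A", "B"], ["A", "B"])
        own = df[(df.true_class == "A") & (df.predicted_class == "A")]
        assert own["median"].iloc[0] == 1.0

    def test_uniform_predictor_medians_quarter(self):
        scores = np.full((8, 4), 0.25)
        truth = ["A", "B", "C", "D"] * 2
        df = cf.class_probability_summary(scores, truth, ["A", "B", "C", "D"])
        assert (df["median"] == 0.25).all()

    def test_separated_class_dominates_own_probability(self, split_4class, small_dl_model):
        _, test = split_4class
        probs = small_dl_model.predict_proba(test)
        df = cf.class_probability_summary(probs, test.labels, list(small_dl_model.classes_))
        for t in df.true_class.unique():
            sub = df[df.true_class == t].set_index("predicted_class")["median"]
            assert sub.idxmax() == t


class TestGedeonImportance:
    def test_two_by_two_toy_matches_hand_computation(self):
        W1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        W2 = np.array([[5.0, 6.0], [7.0, 8.0]])
        # by hand: P1 columns |w|/colsum -> [[1/4, 2/6], [3/4, 4/6]];
        # P2 row sums of column-normalized |W2|: (5/12 + 6/14, 7/12 + 8/14)
        q1, q2 = 5 / 12 + 6 / 14, 7 / 12 + 8 / 14
        expected = np.array([0.25 * q1 + (2 / 6) * q2, 0.75 * q1 + (4 / 6) * q2])
        np.testing.assert_allclose(gedeon_scores(W1, W2), expected, rtol=1e-12)

    def test_zero_weight_blocks_score_zero(self, split_4class):
        train, _ = split_4class
        spec = cf.ModelSpec("DL", {"hidden": (8, 4, 3), "epochs": 1}, seed=0)
        clf = cf.train(spec, train.subset(np.arange(40)))
        # zero out all first-layer weights from SSC and AmCyan inputs
        b = train.chunk_size
        clf.backend.Ws[0][b:, :] = 0.0
        rep = cf.gedeon_importance(clf, chunk_size=b)
        assert rep.per_block["SSC-A"] == 0.0
        assert rep.per_block["AmCyan-A"] == 0.0
        assert rep.per_block["FSC-A"] > 0

    def test_block_sums_invariant_to_within_block_permutation(self):
        rng = np.random.default_rng(0)
        W1, W2 = rng.normal(size=(6, 4)), rng.normal(size=(4, 3))
        base = gedeon_scores(W1, W2)
        perm = np.r_[rng.permutation(3), 3 + rng.permutation(3)]  # two blocks of 3
        permuted = gedeon_scores(W1[perm], W2)
        assert base[:3].sum() == pytest.approx(permuted[:3].sum())
        assert base[3:].sum() == pytest.approx(permuted[3:].sum())

    def test_normalization_and_block_aggregation(self, small_dl_model):
        rep = cf.gedeon_importance(small_dl_model, chunk_size=1000)
        assert rep.per_variable.max() == pytest.approx(1.0)
        assert (rep.per_variable >= 0).all()
        for i, ch in enumerate(cf.ANALYSIS_CHANNELS):
            block = rep.per_variable[i * 1000 : (i + 1) * 1000].sum()
            assert rep.per_block[ch] == pytest.approx(block)

    def test_fsc_only_separation_ranks_fsc_block_highest(self):
        """When only the FSC block carries class signal, its importance
        block must dominate after training."""
        rng = np.random.default_rng(1)
        n, b = 120, 10
        y = np.repeat(["A", "B"], n // 2)
        X = rng.normal(size=(n, 3 * b))
        X[y == "B", :b] += 4.0  # signal confined to the FSC block
        ds = cf.LabeledDataset(
            X=X, labels=y.astype(object),
            provenance=pd.DataFrame(
                {"sample_id": "s", "replicate": 1, "timepoint": 0,
                 "chunk_index": range(n)}
            ),
            chunk_size=b,
        )
        clf = cf.train(cf.ModelSpec("DL", {"hidden": (16, 8, 4), "epochs": 30}, seed=0), ds)
        rep = cf.gedeon_importance(clf, chunk_size=b)
        assert rep.per_block["FSC-A"] == max(rep.per_block.values())

    def test_non_dl_model_rejected(self, split_4class):
        train, _ = split_4class
        clf = cf.train(cf.ModelSpec("NB"), train)
        with pytest.raises(TypeError, match="feed-forward"):
            cf.gedeon_importance(clf)


class TestReportTables:
    def test_accuracy_table_layout(self):
        per_model = {
            "GB": (0.7126, {"ACETO": 0.4187, "ACIDO": 0.9120}),
            "NB": (0.6044, {"ACETO": 0.6387, "ACIDO": 0.9707}),
        }
        t = cf.evaluation.accuracy_table(per_model)
        assert list(t.columns) == ["GB", "NB"]
        assert list(t.index) == ["ACETO", "ACIDO", "Overall"]
        assert t.loc["Overall", "GB"] == pytest.approx(0.7126)
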