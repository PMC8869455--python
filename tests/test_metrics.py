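"""Confusion-matrix statistics, inception score, class coverage.

The worked numerical examples use the published three-class brain-tumor
evaluation (test counts 286/142/186): 220 correct gliomas give recall
220/286 = 0.7692308, etc.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgan import metrics as m
from edgan.metrics import (
    ConfusionMatrix,
    DegenerateRateWarning,
    accuracy,
    class_coverage,
    f1_score,
    format_percent,
    inception_score,
    one_vs_rest,
    precision,
    report,
    sensitivity,
    specificity,
)


class TestConfusionMatrix:
    def test_from_labels_and_invariants(self):
        cm = ConfusionMatrix.from_labels([0, 0, 1, 2, 2], [0, 1, 1, 2, 0],
                                         ("a", "b", "c"))
        assert cm.total == 5
        for i in range(3):
            tp, fp, fn, tn = one_vs_rest(cm, i)
            assert tp + fn == cm.counts[i].sum()
            assert tp + fp == cm.counts[:, i].sum()
            assert tp + fp + fn + tn == cm.total

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1], [0, 2]]))

    def test_index_out_of_range(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int))
        with pytest.raises(IndexError):
            one_vs_rest(cm, 3)


class TestOneVsRest:
    def test_published_glioma_row_reduction(self):
        # 220 of 286 gliomas correct; errors split 36 meningioma / 30 pituitary
        cm = ConfusionMatrix(np.array([[220, 36, 30],
                                       [0, 142, 0],
                                       [0, 0, 186]]))
        tp, fp, fn, tn = one_vs_rest(cm, 0)
        assert (tp, fn) == (220, 66)

    def test_identity_matrix(self):
        cm = ConfusionMatrix(np.diag([10, 10, 10]))
        assert one_vs_rest(cm, 0) == (10, 0, 0, 20)

    def test_all_zero_matrix(self):
        cm = ConfusionMatrix(np.zeros((3, 3), dtype=int))
        assert one_vs_rest(cm, 1) == (0, 0, 0, 0)


class TestRates:
    def test_published_glioma_sensitivity(self):
        assert sensitivity(220, 66) == pytest.approx(0.7692308, abs=5e-8)

    def test_zero_denominator_flags_degenerate(self):
        with pytest.warns(DegenerateRateWarning):
            assert sensitivity(0, 0) == 0.0
        with pytest.warns(DegenerateRateWarning):
            assert precision(0, 0) == 0.0
        with pytest.warns(DegenerateRateWarning):
            assert specificity(0, 0) == 0.0

    def test_negative_counts_rejected(self):
        for fn in (sensitivity, specificity, precision):
            with pytest.raises(ValueError):
                fn(-1, 2)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_rates_bounded_in_unit_interval(self, tp, fp, fn, tn):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for v in (sensitivity(tp, fn), specificity(tn, fp), precision(tp, fp)):
                assert 0.0 <= v <= 1.0


class TestF1:
    def test_published_meningioma_value(self):
        assert f1_score(0.5865922, 0.7394366) == pytest.approx(0.6542056, abs=5e-8)

    def test_published_pituitary_value(self):
        assert f1_score(0.7076023, 0.6505376) == pytest.approx(0.6778711, abs=5e-8)

    def test_perfect_scores(self):
        assert f1_score(1.0, 1.0) == 1.0
        assert f1_score(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_harmonic_mean_below_arithmetic_mean(self, p, r):
        assert f1_score(p, r) <= (p + r) / 2 + 1e-12


class TestAccuracyAndReport:
    def test_published_no_augmentation_average_accuracy(self):
        """Recalls 0.7692308/0.7394366/0.6505376 at test counts 286/142/186
        imply 446/614 correct = 72.63% (truncated display)."""
        recalls = (0.7692308, 0.7394366, 0.6505376)
        counts = (286, 142, 186)
        correct = [round(r * n) for r, n in zip(recalls, counts)]
        assert correct == [220, 105, 121]
        cm = np.zeros((3, 3), dtype=int)
        for i, (c, n) in enumerate(zip(correct, counts)):
            cm[i, i] = c
            cm[i, (i + 1) % 3] = n - c
        acc = accuracy(ConfusionMatrix(cm))
        assert acc == pytest.approx(446 / 614 * 100, abs=1e-9)
        assert format_percent(acc) == "72.63"

    def test_published_full_augmentation_average_accuracy(self):
        recalls = (0.965035, 0.964789, 0.956989)
        counts = (286, 142, 186)
        correct = [round(r * n) for r, n in zip(recalls, counts)]
        assert correct == [276, 137, 178]
        assert sum(correct) / sum(counts) * 100 == pytest.approx(96.254, abs=1e-2)
        assert format_percent(sum(correct) / sum(counts) * 100) == "96.25"

    def test_diagonal_matrix_is_perfect(self):
        rep = report(ConfusionMatrix(np.diag([5, 6, 7])))
        assert rep.average_accuracy == 100.0
        for row in rep.per_class:
            assert row["recall"] == row["precision"] == row["f1"] == 1.0

    def test_one_error_in_ten(self):
        cm = ConfusionMatrix(np.array([[4, 1], [0, 5]]))
        assert accuracy(cm) == pytest.approx(90.0)

    def test_report_serialization(self, tmp_path):
        rep = report(ConfusionMatrix(np.diag([2, 2, 2])))
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        assert (tmp_path / "r.json").exists()
        text = (tmp_path / "r.csv").read_text()
        assert "average_accuracy_percent,100" in text

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force_pair_enumeration(self, pairs):
        """One-vs-rest counts from the matrix match direct enumeration of
        (true, predicted) label pairs."""
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        cm = ConfusionMatrix.from_labels(y_true, y_pred, ("a", "b", "c"))
        for c in range(3):
            tp = sum(1 for t, p in pairs if t == c and p == c)
            fp = sum(1 for t, p in pairs if t != c and p == c)
            fn = sum(1 for t, p in pairs if t == c and p != c)
            tn = sum(1 for t, p in pairs if t != c and p != c)
            assert one_vs_rest(cm, c) == (tp, fp, fn, tn)
        assert accuracy(cm) == pytest.approx(
            100.0 * sum(t == p for t, p in pairs) / len(pairs))


class _FixedScorer:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        n = len(X)
        reps = int(np.ceil(n / len(self.probs)))
        return np.tile(self.probs, (reps, 1))[:n]


class TestInceptionScore:
    def test_uniform_scorer_scores_exactly_one(self):
        scorer = _FixedScorer([[1 / 3, 1 / 3, 1 / 3]])
        res = inception_score(np.zeros((30, 4, 4)), scorer, n_splits=5)
        assert res.mean == pytest.approx(1.0, abs=1e-12)
        assert res.std == pytest.approx(0.0, abs=1e-12)

    def test_balanced_one_hot_scorer_scores_class_count(self):
        scorer = _FixedScorer(np.eye(3))
        res = inception_score(np.zeros((30, 4, 4)), scorer, n_splits=5)
        assert res.mean == pytest.approx(3.0, rel=1e-9)

    def test_fewer_images_than_splits_rejected(self):
        with pytest.raises(ValueError):
            inception_score(np.zeros((3, 4, 4)), _FixedScorer(np.eye(3)), n_splits=10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_hold_for_random_scorers(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(3), size=40)
        res = inception_score(np.zeros((40, 2, 2)), _FixedScorer(probs), n_splits=4)
        assert 1.0 - 1e-9 <= res.mean <= 3.0 + 1e-9


class TestClassCoverage:
    def test_perfect_stub_covers_everything(self):
        labels = np.repeat([0, 1, 2], 10)
        scorer = _FixedScorer(np.eye(3)[labels])
        out = class_coverage(labels, np.zeros((30, 2, 2)), scorer)
        assert out["coverage"] == 1.0
        assert all(v == 1.0 for v in out["fidelity"].values())

    def test_wrong_class_predictor_scores_zero(self):
        labels = np.zeros(10, dtype=int)
        scorer = _FixedScorer([[0, 1, 0]])
        out = class_coverage(labels, np.zeros((10, 2, 2)), scorer)
        assert out["fidelity"][0] == 0.0
        assert out["coverage"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            class_coverage(np.empty(0, dtype=int), np.empty((0, 2, 2)),
                           _FixedScorer(np.eye(3)))

    def test_copied_exemplars_match_scorer_accuracy(self, scorer, desk_test):
        """A generator stub that replays real class exemplars has fidelity
        equal to the scorer's own per-class accuracy on those images."""
        X, y = desk_test.images(), desk_test.label_indices()
        out = class_coverage(y, X, scorer)
        pred = scorer.predict(X)
        for c in range(3):
            assert out["fidelity"][c] == pytest.approx((pred[y == c] == c).mean())
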