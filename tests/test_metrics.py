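"""Metric suite: hand oracles, published-table worked examples, invariants."""

import numpy as np
import pytest

from bilirad.metrics import (
    ConfusionMatrix,
    MetricsReport,
    accuracy,
    auprc,
    auroc,
    cohens_kappa,
    confusion,
    evaluate,
    one_vs_rest_prf,
)
from bilirad.reports import LABELS, Label


def cm_from_rows(rows):
    return ConfusionMatrix(np.asarray(rows))


class TestConfusion:
    def test_identity_predictions_diagonal(self):
        labels = [Label.NEGATIVE, Label.POSITIVE, Label.OBSCURE, Label.NEGATIVE]
        cm = confusion(labels, labels)
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_empty_inputs(self):
        assert confusion([], []).counts.sum() == 0

    def test_hand_counts(self):
        t = [Label.NEGATIVE, Label.NEGATIVE, Label.POSITIVE, Label.OBSCURE]
        p = [Label.POSITIVE, Label.NEGATIVE, Label.POSITIVE, Label.NEGATIVE]
        cm = confusion(t, p)
        assert np.array_equal(cm.counts, [[1, 1, 0], [0, 1, 0], [1, 0, 0]])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([Label.NEGATIVE], [])


def cm_from_counts(tp, predicted, actual, total=2000):
    """3x3 matrix realizing given one-vs-rest counts for class 0."""
    c = np.zeros((3, 3), dtype=int)
    c[0, 0] = tp
    c[1, 0] = predicted - tp
    c[0, 1] = actual - tp
    c[2, 2] = total - predicted - (actual - tp)
    return ConfusionMatrix(c)


class TestWorkedExamples:
    """Per-class F1 recomputed from published n/N count pairs.

    F1 = 2*TP / (predicted + actual); rows whose printed F1 disagrees with
    their own printed counts are not asserted.
    """

    @pytest.mark.parametrize(
        "tp,predicted,actual,f1_pct,precision_pct,recall_pct",
        [
            # test-set table: negative and obscure rows of the proposed model
            (776, 809, 801, 96, 95.9, 96.9),
            (70, 115, 110, 62, 60.9, 63.6),
            # test-set table: substring-FastText negative / obscure rows
            (776, 819, 801, 96, 94.7, 96.9),
            (52, 73, 110, 57, 71.2, 47.3),
            # test-set table: Word2Vec Bi-LSTM-attention negative / obscure
            (772, 849, 801, 94, 90.9, 96.4),
            (47, 80, 110, 49, 58.8, 42.7),
            # extra-validation table: all three rows are consistent
            (422, 470, 498, 87, 89.8, 84.7),
            (142, 155, 185, 84, 91.6, 76.8),
            (77, 178, 120, 52, 43.3, 64.2),
        ],
    )
    def test_f1_from_count_pairs(self, tp, predicted, actual, f1_pct, precision_pct, recall_pct):
        cm = cm_from_counts(tp, predicted, actual)
        p, r, f1 = one_vs_rest_prf(cm, Label.NEGATIVE)
        assert round(100 * p, 1) == precision_pct
        assert round(100 * r, 1) == recall_pct
        assert round(100 * f1) == f1_pct

    def test_perfect_diagonal(self):
        cm = cm_from_rows(np.diag([5, 3, 2]))
        for lab in LABELS:
            assert one_vs_rest_prf(cm, lab) == (1.0, 1.0, 1.0)

    def test_zero_division_convention(self):
        cm = cm_from_rows([[0, 2, 0], [0, 2, 0], [0, 1, 0]])
        p, r, f1 = one_vs_rest_prf(cm, Label.NEGATIVE)
        assert (p, r, f1) == (0.0, 0.0, 0.0)


class TestAccuracy:
    def test_diagonal_and_offdiagonal(self):
        assert accuracy(cm_from_rows(np.diag([1, 2, 3]))) == 1.0
        assert accuracy(cm_from_rows([[0, 1, 0], [1, 0, 0], [0, 1, 0]])) == 0.0

    def test_hand_value(self):
        cm = cm_from_rows([[5, 1, 0], [2, 3, 1], [0, 0, 4]])
        assert accuracy(cm) == pytest.approx(12 / 16)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            accuracy(cm_from_rows(np.zeros((3, 3), dtype=int)))


def auroc_pair_oracle(scores, positives):
    """O(n^2) Mann-Whitney pair counting, ties counted one half."""
    pos = [s for s, y in zip(scores, positives) if y == 1]
    neg = [s for s, y in zip(scores, positives) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_and_constant(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert auroc(scores, y) == pytest.approx(auroc_pair_oracle(scores, y), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_five_point_hand_example(self):
        # ranked: 1,0,1,1,0 -> AP = (1/1 + 2/3 + 3/4) / 3
        got = auprc([0.9, 0.8, 0.7, 0.6, 0.5], [1, 0, 1, 1, 0])
        assert got == pytest.approx((1 + 2 / 3 + 3 / 4) / 3, abs=1e-12)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(7)
        n, prevalence = 10_000, 0.3
        y = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        assert auprc(scores, y) == pytest.approx(y.mean(), abs=0.02)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            auprc([0.5, 0.6], [0, 0])


class TestKappa:
    def test_identical_labelings(self):
        labels = [Label.NEGATIVE, Label.POSITIVE, Label.OBSCURE, Label.NEGATIVE]
        assert cohens_kappa(labels, labels) == 1.0

    def test_chance_level_hand_example(self):
        # p_o = 0.5, p_e = 0.5 -> kappa = 0
        a = [Label.POSITIVE, Label.POSITIVE, Label.NEGATIVE, Label.NEGATIVE]
        b = [Label.POSITIVE, Label.NEGATIVE, Label.POSITIVE, Label.NEGATIVE]
        assert cohens_kappa(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_complete_binary_disagreement(self):
        a = [Label.POSITIVE, Label.POSITIVE, Label.NEGATIVE, Label.NEGATIVE]
        b = [Label.NEGATIVE, Label.NEGATIVE, Label.POSITIVE, Label.POSITIVE]
        assert cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_constant_equal_raters(self):
        assert cohens_kappa([Label.NEGATIVE] * 5, [Label.NEGATIVE] * 5) == 1.0


class TestEvaluate:
    @staticmethod
    def _random_eval(n=200, seed=3):
        rng = np.random.default_rng(seed)
        true = [LABELS[i] for i in rng.integers(0, 3, n)]
        probs = rng.dirichlet(np.ones(3), size=n)
        preds = [LABELS[int(i)] for i in probs.argmax(axis=1)]
        return evaluate((preds, probs), true), true, preds

    def test_all_correct_fixture(self):
        labels = [LABELS[i % 3] for i in range(30)]
        probs = np.eye(3)[[l.value for l in labels]] * 0.9 + 0.05
        probs /= probs.sum(axis=1, keepdims=True)
        rep = evaluate((labels, probs), labels)
        assert rep.accuracy == 1.0
        for m in rep.per_class.values():
            assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
            assert m.auroc == 1.0

    def test_micro_recall_equals_accuracy(self):
        rep, _, _ = self._random_eval()
        total_tp = sum(m.tp for m in rep.per_class.values())
        total = rep.confusion_matrix.total
        assert total_tp / total == pytest.approx(rep.accuracy)

    def test_f1_bounded_by_precision_recall(self):
        rep, _, _ = self._random_eval(seed=9)
        for m in rep.per_class.values():
            assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_json_roundtrip(self):
        rep, _, _ = self._random_eval()
        again = MetricsReport.from_json(rep.to_json())
        assert again.accuracy == rep.accuracy
        assert again.per_class.keys() == rep.per_class.keys()
        assert np.array_equal(again.confusion_matrix.counts, rep.confusion_matrix.counts)

    def test_markdown_has_count_pairs(self):
        rep, _, _ = self._random_eval()
        md = rep.to_markdown()
        m = rep.per_class["negative"]
        assert f"{m.tp}/{m.predicted}" in md and f"{m.tp}/{m.support}" in md
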