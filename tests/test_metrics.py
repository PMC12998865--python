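import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embedfuse import (
    CorruptionErrorTable,
    UndefinedMetricError,
    accuracy,
    auc_roc,
    balanced_error,
    count_corruption_pairs,
    robustness_scores,
)


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney count: ties between a positive and a negative
    score contribute one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAccuracy:
    def test_perfect_and_fractional(self):
        assert accuracy(np.array([1, 0, 1]), np.array([1, 0, 1])) == 1.0
        assert accuracy(np.array([1, 0, 1, 0]), np.array([1, 0, 0, 0])) == 0.75

    def test_multilabel_counts_label_decisions(self):
        pred = np.array([[1, 0], [1, 1]])
        true = np.array([[1, 0], [0, 1]])  # 3 of 4 label decisions correct
        assert accuracy(pred, true) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(UndefinedMetricError):
            accuracy(np.array([]), np.array([]))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_roc(np.array([0.9, 0.8, 0.2, 0.1]),
                       np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties_give_half(self):
        assert auc_roc(np.full(6, 0.3), np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_hand_counted_pairs(self):
        # pos {0.9, 0.4}, neg {0.5, 0.1}: wins 3 of 4 pairs
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc_roc(scores, labels) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auc_roc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        scores = np.round(rng.uniform(size=n), 2)  # coarse grid forces ties
        assert auc_roc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        base = auc_roc(scores, labels)
        for f in (np.exp, np.tanh, lambda x: 3 * x + 7, lambda x: x**3):
            assert auc_roc(f(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_multiclass_macro_ovr(self):
        scores = np.array([[0.8, 0.1, 0.1],
                           [0.1, 0.8, 0.1],
                           [0.1, 0.1, 0.8],
                           [0.4, 0.4, 0.2]])
        labels = np.array([0, 1, 2, 0])
        assert auc_roc(scores, labels, "multiclass") > 0.8

    def test_multilabel_macro(self):
        scores = np.array([[0.9, 0.1], [0.2, 0.8], [0.7, 0.3], [0.1, 0.9]])
        labels = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        assert auc_roc(scores, labels, "multilabel") == 1.0


class TestBalancedError:
    def test_perfect_predictions(self):
        assert balanced_error(np.array([0, 1, 0, 1]), np.array([0, 1, 0, 1])) == 0.0

    def test_binary_recalls_one_and_half(self):
        # class 0 recall 1.0 (2/2), class 1 recall 0.5 (1/2)
        pred = np.array([0, 0, 1, 0])
        true = np.array([0, 0, 1, 1])
        assert balanced_error(pred, true) == pytest.approx(0.25)

    def test_three_class_confusion(self):
        # recalls 0.9, 0.6, 0.3 -> balanced error 0.4
        true = np.concatenate([np.zeros(10), np.ones(10), np.full(10, 2)])
        pred = true.copy()
        pred[9] = 1          # class 0: 9/10
        pred[10:14] = 0      # class 1: 6/10
        pred[20:27] = 0      # class 2: 3/10
        assert balanced_error(pred, true) == pytest.approx(0.4)

    def test_missing_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            balanced_error(np.array([0, 0]), np.array([0, 0]))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5))
    def test_equals_error_rate_on_balanced_classes(self, seed, k):
        rng = np.random.default_rng(seed)
        per_class = 20
        true = np.repeat(np.arange(k), per_class)
        pred = true.copy()
        # perturb the same number of samples in every class: balance preserved
        flips = int(rng.integers(0, per_class))
        for c in range(k):
            idx = np.where(true == c)[0][:flips]
            pred[idx] = (c + 1) % k
        assert balanced_error(pred, true) == pytest.approx(
            1.0 - accuracy(pred, true), abs=1e-12
        )


class TestRobustness:
    def _self_table(self):
        rng = np.random.default_rng(3)
        errs = rng.uniform(0.1, 0.5, size=(11, 5))
        return CorruptionErrorTable(model_clean=0.08, ref_clean=0.08,
                                    model_errors=errs, ref_errors=errs.copy())

    def test_self_normalisation_is_exactly_one(self):
        be, rbe = robustness_scores(self._self_table())
        assert be == 1.0
        assert rbe == 1.0

    def test_pair_mean_self_normalisation(self):
        be, rbe = robustness_scores(self._self_table(), aggregation="pair_mean")
        assert be == 1.0
        assert rbe == 1.0

    def test_toy_table_hand_computed(self):
        # 2 corruptions x 1 severity; ratios 0.2/0.4 = 0.5 and 0.3/0.2 = 1.5
        table = CorruptionErrorTable(
            model_clean=0.1, ref_clean=0.1,
            model_errors=[[0.2], [0.3]], ref_errors=[[0.4], [0.2]],
        )
        be, rbe = robustness_scores(table)
        assert be == pytest.approx((0.5 + 1.5) / 2)
        # rBE: (0.1/0.3 + 0.2/0.1) / 2
        assert rbe == pytest.approx((0.1 / 0.3 + 0.2 / 0.1) / 2)

    def test_negative_rbe_passes_through(self):
        """A model whose corrupted error drops below its clean error yields a
        negative rBE; it must not be clamped."""
        table = CorruptionErrorTable(
            model_clean=0.3, ref_clean=0.3,
            model_errors=[[0.2]], ref_errors=[[0.5]],
        )
        _, rbe = robustness_scores(table)
        assert rbe == pytest.approx((0.2 - 0.3) / (0.5 - 0.3))
        assert rbe < 0

    def test_scale_100(self):
        be, rbe = robustness_scores(self._self_table(), scale_100=True)
        assert be == 100.0
        assert rbe == 100.0

    def test_zero_reference_denominator_raises(self):
        table = CorruptionErrorTable(model_clean=0.1, ref_clean=0.1,
                                     model_errors=[[0.2]], ref_errors=[[0.0]])
        with pytest.raises(ZeroDivisionError):
            robustness_scores(table)

    def test_csv_round_trip(self, tmp_path):
        table = self._self_table()
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = CorruptionErrorTable.from_csv(path)
        np.testing.assert_allclose(back.model_errors, table.model_errors)
        np.testing.assert_allclose(back.ref_errors, table.ref_errors)
        assert back.model_clean == table.model_clean
        assert back.ref_clean == table.ref_clean

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            CorruptionErrorTable(model_clean=0.1, ref_clean=0.1,
                                 model_errors=[[0.2]], ref_errors=[[0.2], [0.3]])
        with pytest.raises(ValueError):
            CorruptionErrorTable(model_clean=0.1, ref_clean=0.1,
                                 model_errors=[[1.2]], ref_errors=[[0.2]])


def test_corruption_pair_counts():
    assert count_corruption_pairs(11, 5) == 55
    assert count_corruption_pairs(1, 1) == 1
    assert count_corruption_pairs(3, 2) == 6
    with pytest.raises(ValueError):
        count_corruption_pairs(0, 5)
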