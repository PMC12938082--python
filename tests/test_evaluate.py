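"""Split protocol, confusion matrices and metric identities."""

import warnings

import numpy as np
import pytest

from lungsounds.evaluate import (
    ConfusionMatrix,
    SplitConfig,
    compute_metrics,
    confusion_matrix,
    f1_score,
    split_dataset,
    summarize_repeats,
)


def _metrics_oracle(counts):
    """One-vs-rest TP/FP/FN bookkeeping via explicit loops."""
    counts = np.asarray(counts)
    k = len(counts)
    total = counts.sum()
    acc = sum(counts[i, i] for i in range(k)) / total
    out = {}
    for i in range(k):
        tp = counts[i, i]
        fp = sum(counts[j, i] for j in range(k) if j != i)
        fn = sum(counts[i, j] for j in range(k) if j != i)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        out[i] = (p, r, f)
    return acc, out


class TestSplitDataset:
    def test_400_cycles_at_80_10_10(self):
        labels = np.repeat(np.arange(4), 100)
        tr, va, te = split_dataset(labels, SplitConfig(seed=3))
        assert (len(tr), len(va), len(te)) == (320, 40, 40)

    def test_stratified_ten_test_items_per_class(self):
        labels = np.repeat(np.arange(4), 100)
        _, _, te = split_dataset(labels, SplitConfig(seed=5))
        for c in range(4):
            assert (labels[te] == c).sum() == 10

    def test_partition_disjoint_and_exhaustive(self):
        labels = np.repeat(np.arange(4), 25)
        tr, va, te = split_dataset(labels, SplitConfig(seed=1))
        all_idx = np.concatenate([tr, va, te])
        assert len(set(all_idx)) == len(labels)
        assert sorted(all_idx) == list(range(len(labels)))

    def test_deterministic_per_seed_and_repeat(self):
        labels = np.repeat(np.arange(4), 30)
        a = split_dataset(labels, SplitConfig(seed=9), repeat_index=2)
        b = split_dataset(labels, SplitConfig(seed=9), repeat_index=2)
        c = split_dataset(labels, SplitConfig(seed=9), repeat_index=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_infeasible_fractions_rejected(self):
        labels = np.repeat(np.arange(4), 5)  # 5 per class cannot fill 10% slots
        with pytest.raises(ValueError):
            split_dataset(labels, SplitConfig(seed=0))

    def test_subject_level_units_stay_together(self):
        labels = np.repeat(np.arange(2), 50)
        groups = np.concatenate([np.repeat(np.arange(10), 5), np.repeat(np.arange(10, 20), 5)])
        tr, va, te = split_dataset(
            labels, SplitConfig(unit="subject", seed=4), groups=groups
        )
        for part in (tr, va, te):
            for g in np.unique(groups[part]):
                assert (groups == g).sum() == (groups[part] == g).sum()


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 2], [0, 1, 2, 2], class_order=[0, 1, 2])
        assert np.array_equal(cm.counts, np.diag([1, 1, 2]))

    def test_class_order_permutation_consistent(self):
        t = ["a", "b", "a", "c"]
        p = ["b", "b", "a", "c"]
        cm1 = confusion_matrix(t, p, ["a", "b", "c"])
        cm2 = confusion_matrix(t, p, ["c", "a", "b"])
        perm = [cm2.class_labels.index(c) for c in cm1.class_labels]
        assert np.array_equal(cm2.counts[np.ix_(perm, perm)], cm1.counts)

    def test_counts_match_counting_loop(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        cm = confusion_matrix(t, p, class_order=list(range(4)))
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == int(np.sum((t == i) & (p == j)))
        assert np.array_equal(cm.row_sums(), np.bincount(t, minlength=4))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 0], class_order=[0, 1])


class TestComputeMetrics:
    def test_printed_f1_worked_examples(self):
        assert round(f1_score(0.91, 1.00), 2) == 0.95
        assert round(f1_score(0.75, 0.90), 2) == 0.82
        assert round(f1_score(1.00, 0.60), 2) == 0.75

    def test_perfect_diagonal_all_ones(self):
        cm = ConfusionMatrix(np.diag([10, 10, 10, 10]), list("abcd"))
        m = compute_metrics(cm)
        assert m.accuracy == 1.0
        assert all(v == 1.0 for v in m.precision.values())
        assert all(v == 1.0 for v in m.f1.values())

    def test_single_off_diagonal_error_arithmetic(self):
        """Counts: diag 10,9,10,10 with one rhonchi->normal error."""
        counts = np.diag([10, 9, 10, 10])
        counts[1, 0] = 1
        cm = ConfusionMatrix(counts, ["normal", "rhonchi", "fine_crackle", "coarse_crackle"])
        m = compute_metrics(cm)
        assert m.accuracy == pytest.approx(39 / 40)
        assert m.recall["rhonchi"] == pytest.approx(0.9)
        assert m.precision["normal"] == pytest.approx(10 / 11)

    def test_agrees_with_bruteforce_oracle_randomized(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 51, (k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, list(range(k)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(cm)
            acc, per_class = _metrics_oracle(counts)
            assert m.accuracy == pytest.approx(acc)
            for i in range(k):
                p, r, f = per_class[i]
                assert m.precision[i] == pytest.approx(p)
                assert m.recall[i] == pytest.approx(r)
                assert m.f1[i] == pytest.approx(f)

    def test_micro_average_identity(self):
        """Single-label: accuracy equals micro-averaged recall (trace/total)."""
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, (4, 4))
        cm = ConfusionMatrix(counts, list(range(4)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(cm)
        micro_recall = np.trace(counts) / counts.sum()
        assert m.accuracy == pytest.approx(micro_recall)

    def test_zero_denominator_warns_and_zeroes(self):
        counts = np.array([[5, 0], [3, 0]])  # class 1 never predicted
        cm = ConfusionMatrix(counts, ["a", "b"])
        with pytest.warns(UserWarning):
            m = compute_metrics(cm)
        assert m.precision["b"] == 0.0
        assert m.f1["b"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"]))


class TestRepeatSummary:
    def test_single_repeat_zero_std(self):
        mean, std, rep = summarize_repeats([0.9])
        assert (mean, std, rep) == (90.0, 0.0, 0)

    def test_two_repeat_tie_takes_lower_index(self):
        mean, std, rep = summarize_repeats([0.9, 1.0])
        assert mean == pytest.approx(95.0)
        assert rep == 0  # both are 0.05 from the mean; tie -> lower index

    def test_mean_std_recomputable(self):
        accs = [0.8, 0.85, 0.9, 0.95]
        mean, std, rep = summarize_repeats(accs)
        assert mean == pytest.approx(100 * np.mean(accs))
        assert std == pytest.approx(100 * np.std(accs, ddof=1))
        assert rep == int(np.argmin(np.abs(np.array(accs) - np.mean(accs))))
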