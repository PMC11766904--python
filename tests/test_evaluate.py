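"""Split-plan properties, LNSO bookkeeping, and the summary statistics."""

import numpy as np
import pytest

from eegdem.evaluate import (
    class_metrics,
    make_splits,
    problem_label,
    run_lnso,
    summarize,
)
from eegdem.io import SubjectMeta


def metas_for(counts):
    return [SubjectMeta(f"{g}-{i:02d}", g) for g, n in counts.items()
            for i in range(n)]


class TestSplits:
    def test_partition_and_stratification(self):
        metas = metas_for({"AD": 36, "FTD": 23, "CN": 29})
        plan = make_splits(metas, 5, seed=0)
        test_sets = [set(plan.test_subjects(k)) for k in range(5)]
        # pairwise disjoint, union covers everyone
        assert sum(len(s) for s in test_sets) == 88
        assert set.union(*test_sets) == {m.subject_id for m in metas}
        for k in range(5):
            assert not (test_sets[k] & set(plan.train_subjects(k)))
            # per-group counts differ by ≤ 1 across folds
        for g, n in {"AD": 36, "FTD": 23, "CN": 29}.items():
            per_fold = [sum(1 for s in ts if s.startswith(g))
                        for ts in test_sets]
            assert max(per_fold) - min(per_fold) <= 1
        # overall fold sizes: 36/5, 23/5, 29/5 pigeonhole → spread ≤ 3
        sizes = [len(s) for s in test_sets]
        assert max(sizes) - min(sizes) <= 3

    def test_loso_degenerate_case(self):
        metas = metas_for({"CN": 6})
        plan = make_splits(metas, 6, seed=1)
        assert plan.k == 6
        assert all(len(plan.test_subjects(k)) == 1 for k in range(6))

    def test_group_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            make_splits(metas_for({"AD": 3, "CN": 10}), 5, seed=0)

    def test_seeded_reproducibility(self):
        metas = metas_for({"AD": 10, "CN": 10})
        a = make_splits(metas, 5, seed=7)
        b = make_splits(metas, 5, seed=7)
        c = make_splits(metas, 5, seed=8)
        assert a.folds == b.folds
        assert a.folds != c.folds


class _PerfectStub:
    """Ignores training; predicts the label encoded in the feature."""

    def fit(self, x, y):
        return self

    def predict(self, x):
        return x[:, 0].astype(int)


class _MajorityStub:
    def fit(self, x, y):
        self._mode = np.bincount(y).argmax()
        return self

    def predict(self, x):
        return np.full(len(x), self._mode)


def epoch_dataset(counts, epochs_per_subject):
    """Feature = class index, one row per epoch."""
    xs, labels, subjects = [], [], []
    classes = sorted(counts)
    for ci, g in enumerate(classes):
        for i in range(counts[g]):
            sid = f"{g}-{i:02d}"
            for _ in range(epochs_per_subject[g]):
                xs.append([ci])
                labels.append(g)
                subjects.append(sid)
    return (np.array(xs, dtype=float), np.array(labels),
            np.array(subjects), metas_for(counts))


class TestRunLnso:
    def test_perfect_classifier_scores_one(self):
        x, labels, subjects, metas = epoch_dataset(
            {"AD": 5, "CN": 5}, {"AD": 4, "CN": 4})
        plan = make_splits(metas, 5, seed=0)
        report = run_lnso(lambda k: _PerfectStub(), x, labels, subjects, plan)
        assert report.fold_accuracies == [1.0] * 5
        assert np.all(report.pooled_confusion == np.diag([20, 20]))

    def test_majority_stub_pooled_accuracy_is_class_share(self):
        # 36 AD subjects × 20 epochs = 720, 29 CN × 20 = 580
        x, labels, subjects, metas = epoch_dataset(
            {"AD": 36, "CN": 29}, {"AD": 20, "CN": 20})
        plan = make_splits(metas, 5, seed=0)
        report = run_lnso(lambda k: _MajorityStub(), x, labels, subjects, plan)
        assert report.pooled_accuracy == pytest.approx(720 / 1300)

    def test_pooled_matrix_is_sum_of_folds(self):
        x, labels, subjects, metas = epoch_dataset(
            {"AD": 6, "CN": 7}, {"AD": 3, "CN": 5})
        plan = make_splits(metas, 5, seed=2)
        report = run_lnso(lambda k: _MajorityStub(), x, labels, subjects, plan)
        assert np.array_equal(report.pooled_confusion,
                              np.sum(report.fold_confusions, axis=0))
        # each fold's row sums equal that fold's per-class test epoch counts
        for k, conf in enumerate(report.fold_confusions):
            for ci, cls in enumerate(report.classes):
                n_imgs = sum((labels == cls) & np.isin(
                    subjects, list(plan.test_subjects(k))))
                assert conf[ci].sum() == n_imgs


class TestSummarize:
    # the published per-fold accuracies and their printed summary rows
    @pytest.mark.parametrize("folds,expected", [
        ([85.96, 70.31, 86.08, 74.15, 80.73], (79.45, 7.06, 8.77, 70.68, 88.22)),
        ([78.12, 71.18, 70.27, 72.00, 72.66], (72.85, 3.08, 3.82, 69.02, 76.67)),
        ([83.17, 78.28, 83.00, 79.76, 79.27], (80.69, 2.25, 2.79, 77.91, 83.48)),
    ])
    def test_reproduces_printed_summary_rows(self, folds, expected):
        mean, sd, ci, lo, hi = summarize(folds)
        for got, want in zip((mean, sd, ci, lo, hi), expected):
            assert got == pytest.approx(want, abs=0.02)

    def test_identical_folds_have_zero_spread(self):
        mean, sd, ci, lo, hi = summarize([80.0] * 5)
        assert (mean, sd, ci) == (80.0, 0.0, 0.0)
        assert lo == hi == 80.0

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestClassMetrics:
    def test_perfect_diagonal(self):
        m = class_metrics(np.diag([50, 50]))
        assert np.allclose(m["ppv"], 1.0) and np.allclose(m["tpr"], 1.0)
        assert np.allclose(m["f1"], 1.0) and m["macro_f1"] == 1.0

    def test_hand_arithmetic(self):
        m = class_metrics(np.array([[40, 10], [20, 30]]))
        assert m["ppv"][0] == pytest.approx(40 / 60)
        assert m["tpr"][0] == pytest.approx(40 / 50)
        expected_f1 = 2 * (2 / 3) * (4 / 5) / ((2 / 3) + (4 / 5))
        assert m["f1"][0] == pytest.approx(expected_f1)

    def test_empty_predicted_column_flagged_undefined(self):
        conf = np.array([[5, 0, 3], [1, 0, 2], [0, 0, 9]])
        m = class_metrics(conf)
        assert np.isnan(m["ppv"][1])
        # macro mean excludes the undefined entry
        assert m["macro_ppv"] == pytest.approx(
            np.mean([5 / 6, 9 / 14]))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(np.ones((2, 3)))
        with pytest.raises(ValueError):
            class_metrics(np.array([[1, -1], [0, 1]]))


class TestProblemMapping:
    def test_merges_and_exclusions(self):
        assert problem_label("AD", "adftd_cn") == "AD+FTD"
        assert problem_label("FTD", "adftd_cn") == "AD+FTD"
        assert problem_label("FTD", "ad_cn") is None
        assert problem_label("CN", "ad_ftd_cn") == "CN"
        with pytest.raises(ValueError):
            problem_label("AD", "nope")
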