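import numpy as np
import pytest

from mirclass.classifiers import ClassifierSpec, fit_model
from mirclass.core import KIND_GENE, FeatureTable
from mirclass.evaluation import (
    accuracy_pct,
    cross_validate,
    roc_auc,
    stratified_kfold,
    validate_holdout,
)
from conftest import random_binary_table


def auc_pairwise_oracle(scores, labels):
    """Mann–Whitney: wins plus half-ties over positive×negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAccuracyPct:
    @pytest.mark.parametrize("correct,total,expected", [
        (83, 88, 94.32), (64, 88, 72.73), (47, 88, 53.41), (0, 10, 0.0),
    ])
    def test_count_to_percent(self, correct, total, expected):
        assert accuracy_pct(correct, total) == expected

    def test_half_up_rounding(self):
        assert accuracy_pct(1, 800) == 0.13  # 0.125 rounds half-up, not to even
        assert accuracy_pct(1, 16) == 6.25

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy_pct(0, 0)

    def test_correct_above_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy_pct(5, 4)


class TestStratifiedKFold:
    def test_balanced_88_cohort_fold_shape(self):
        labels = ["selected"] * 44 + ["random"] * 44
        folds = stratified_kfold(labels, k=10, seed=0)
        assert len(folds) == 10
        for fold in folds:
            assert len(fold) in (8, 9)
            n_sel = sum(1 for i in fold if labels[i] == "selected")
            assert n_sel in (4, 5)
            assert len(fold) - n_sel in (4, 5)

    def test_folds_partition_indices(self):
        labels = ["selected"] * 25 + ["random"] * 31
        folds = stratified_kfold(labels, k=7, seed=3)
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(56))

    def test_same_seed_identical_folds(self):
        labels = ["selected"] * 20 + ["random"] * 20
        f1 = stratified_kfold(labels, k=5, seed=9)
        f2 = stratified_kfold(labels, k=5, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(["selected", "random"], k=1)

    def test_small_class_reduces_k(self, caplog):
        labels = ["selected"] * 3 + ["random"] * 20
        with caplog.at_level("WARNING"):
            folds = stratified_kfold(labels, k=10, seed=0)
        assert len(folds) == 3


class TestRocAuc:
    def test_perfect_separation(self):
        points, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[0][:2] == (0.0, 0.0)
        assert points[-1][:2] == (1.0, 1.0)

    def test_all_tied_scores_give_half(self):
        _, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        points, _ = roc_auc(rng.random(25), rng.integers(0, 2, 25) | np.arange(25) % 2)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_trapezoid_equals_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 21))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = np.round(rng.random(n), 1)  # ties likely
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCrossValidate:
    def test_pooled_predictions_cover_every_row(self, default_table):
        from mirclass.feature_select import best_first_select
        sel = default_table.select_columns(
            best_first_select(default_table).feature_indices
        )
        rep = cross_validate(ClassifierSpec("naive_bayes", seed=0), sel, k=10, seed=1)
        assert rep.total == default_table.n_rows
        assert sum(sum(row) for row in rep.confusion) == rep.total
        assert rep.confusion[0][0] + rep.confusion[1][1] == rep.correct
        assert rep.accuracy_pct == accuracy_pct(rep.correct, rep.total)
        assert sum(f.total for f in rep.per_fold) == rep.total

    def test_uninformative_features_give_chance_accuracy(self):
        # constant feature: with every training fold balanced (80 rows, 10
        # folds of 4/4), posteriors are exactly the 50/50 prior, every row
        # gets the same fixed class, and the balanced table scores 50.00
        n = 80
        table = FeatureTable(
            row_ids=[f"r{i}" for i in range(n)],
            feature_names=["g"],
            matrix=np.zeros((n, 1)),
            labels=["selected", "random"] * (n // 2),
            column_kinds=[KIND_GENE],
        )
        rep = cross_validate(ClassifierSpec("naive_bayes", seed=0), table, k=10, seed=0)
        assert rep.accuracy_pct == 50.0

    def test_label_permutation_drives_accuracy_to_chance(self, default_table):
        rng = np.random.default_rng(0)
        permuted = FeatureTable(
            row_ids=list(default_table.row_ids),
            feature_names=list(default_table.feature_names),
            matrix=default_table.matrix.copy(),
            labels=[default_table.labels[i]
                    for i in rng.permutation(default_table.n_rows)],
            column_kinds=list(default_table.column_kinds),
        )
        rep = cross_validate(ClassifierSpec("naive_bayes", seed=0), permuted, k=10, seed=1)
        assert 35.0 <= rep.accuracy_pct <= 65.0


class TestValidateHoldout:
    def test_report_covers_all_validation_rows(self):
        train = random_binary_table(40, 5, seed=0)
        val = random_binary_table(18, 5, seed=99)
        model = fit_model(ClassifierSpec("naive_bayes", seed=0), train)
        rep = validate_holdout(model, val)
        assert rep.total == 18
        assert 0.0 <= rep.auc <= 1.0

    def test_column_mismatch_named_in_error(self):
        train = random_binary_table(30, 4, seed=0)
        val = random_binary_table(10, 3, seed=1)
        model = fit_model(ClassifierSpec("naive_bayes", seed=0), train)
        with pytest.raises(ValueError, match="f3"):
            validate_holdout(model, val)
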