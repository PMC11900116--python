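import math

import numpy as np
import pytest

from mirclass.classifiers import (
    AdaBoostM1,
    ClassifierSpec,
    HoeffdingTree,
    NaiveBayes,
    PerfectWeakLearner,
    RandomForest,
    RandomTree,
    SequentialNet,
    adaboost_round,
    fit_model,
    hoeffding_bound,
    init_sequential_weights,
    sequential_forward,
)
from conftest import tiny_numeric_table


class TestNaiveBayes:
    def test_symmetric_data_gives_half(self):
        # identical feature distribution per class, equal priors
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        y = np.array([0, 0, 1, 1])
        nb = NaiveBayes().fit(X, y)
        p = nb.predict_proba_rows(np.array([[1.0], [0.0]]))
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_toy_posteriors_match_hand_bayes_arithmetic(self):
        # class 1: (1,1),(1,0),(1,1); class 0: (0,0),(0,1),(0,0)
        # add-1: P(f1=1|1)=4/5, P(f2=1|1)=3/5, P(f1=1|0)=1/5, P(f2=1|0)=2/5
        X = np.array([[1, 1], [1, 0], [1, 1], [0, 0], [0, 1], [0, 0]], dtype=float)
        y = np.array([1, 1, 1, 0, 0, 0])
        nb = NaiveBayes().fit(X, y)
        p = nb.predict_proba_rows(np.array([[1, 1], [0, 0], [1, 0]], dtype=float))
        np.testing.assert_allclose(p, [6 / 7, 1 / 7, 8 / 11], atol=1e-12)

    def test_unseen_value_has_finite_posterior(self):
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        y = np.array([1, 1, 0, 0])
        nb = NaiveBayes().fit(X, y)
        p = nb.predict_proba_rows(np.array([[0.0]]))  # value unseen in class 1
        assert 0.0 < p[0] < 1.0

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([
            rng.integers(0, 2, 50).astype(float),
            rng.normal(size=50),
        ])
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        nb = NaiveBayes().fit(X, y)
        post = nb.posteriors(X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            NaiveBayes().fit(np.zeros((3, 1)), np.array([1, 1, 1]))


class TestHoeffdingBound:
    def test_closed_form(self):
        assert hoeffding_bound(1.0, 0.05, 1000) == pytest.approx(
            math.sqrt(math.log(20) / 2000), abs=1e-12
        )

    def test_monotone_decreasing_in_n(self):
        eps = [hoeffding_bound(1.0, 0.05, n) for n in (1, 10, 100, 1000, 10000)]
        assert all(a > b for a, b in zip(eps, eps[1:]))

    def test_delta_near_one_gives_vanishing_epsilon(self):
        assert hoeffding_bound(1.0, 1 - 1e-12, 100) < 1e-6

    @pytest.mark.parametrize("R,delta,n", [(0, 0.05, 10), (1, 0.0, 10),
                                           (1, 1.0, 10), (1, 0.05, 0)])
    def test_domain_violations(self, R, delta, n):
        with pytest.raises(ValueError):
            hoeffding_bound(R, delta, n)


class TestHoeffdingTree:
    def test_learns_single_informative_binary_feature(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 2, n)
        X = np.column_stack([
            np.where(rng.random(n) < 0.95, y, 1 - y).astype(float),
            rng.integers(0, 2, n).astype(float),
        ])
        tree = HoeffdingTree().fit(X, y, bin_edges=[np.array([0.5])] * 2)
        acc = ((tree.predict_proba_rows(X) >= 0.5).astype(int) == y).mean()
        assert acc >= 0.9

    def test_split_governed_by_bound(self):
        # a handful of rows cannot exceed the bound: tree stays a leaf and
        # predicts the class prior
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        y = np.array([1, 0, 1, 0])
        tree = HoeffdingTree(grace_period=100, n_passes=1).fit(
            X, y, bin_edges=[np.array([0.5])]
        )
        p = tree.predict_proba_rows(X)
        np.testing.assert_allclose(p, 0.5, atol=1e-12)


class TestAdaBoostRound:
    def test_beta_closed_form(self):
        w = np.full(4, 0.25)
        correct = np.array([True, True, True, False])
        new_w, beta = adaboost_round(w, correct)  # ε = 0.25
        assert beta == pytest.approx(1 / 3)
        # correct weights shrink ×β before renormalization:
        # raw = [1/12, 1/12, 1/12, 1/4], sum = 1/2
        np.testing.assert_allclose(new_w, [1 / 6, 1 / 6, 1 / 6, 1 / 2])

    def test_weights_renormalized(self):
        rng = np.random.default_rng(1)
        w = rng.random(10)
        w /= w.sum()
        correct = rng.random(10) < 0.8
        if correct.all():
            correct[0] = False
        new_w, _ = adaboost_round(w, correct)
        assert new_w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_error_at_half_aborts(self):
        w = np.full(2, 0.5)
        with pytest.raises(ValueError):
            adaboost_round(w, np.array([True, False]))  # ε = 0.5

    def test_perfect_learner_flagged(self):
        w = np.full(3, 1 / 3)
        with pytest.raises(PerfectWeakLearner):
            adaboost_round(w, np.array([True, True, True]))

    def test_committee_boosts_separable_data(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(80, 4)).astype(float)
        y = (X[:, 0] + X[:, 1] >= 1).astype(int)
        model = AdaBoostM1(n_rounds=10, seed=0).fit(X, y)
        acc = ((model.predict_proba_rows(X) >= 0.5).astype(int) == y).mean()
        assert acc >= 0.95


class TestSequentialNetwork:
    def test_zero_weights_output_half(self):
        weights = [(np.zeros_like(W), np.zeros_like(b))
                   for W, b in init_sequential_weights(2, seed=0)]
        assert sequential_forward(weights, np.array([3.0, -1.0])) == 0.5

    def test_forward_matches_hand_matrix_chain(self):
        weights = init_sequential_weights(2, seed=4)
        row = np.array([0.7, -1.2])
        # independent explicit chain
        a = row
        for W, b in weights[:-1]:
            a = np.maximum(a @ W + b, 0.0)
        z = (a @ weights[-1][0] + weights[-1][1]).item()
        expected = 1.0 / (1.0 + math.exp(-z))
        assert sequential_forward(weights, row) == pytest.approx(expected, abs=1e-12)

    def test_output_strictly_in_unit_interval(self):
        weights = init_sequential_weights(3, seed=1)
        # huge inputs would saturate the sigmoid without clipping
        for scale in (1.0, 1e6):
            p = sequential_forward(weights, scale * np.array([1.0, -2.0, 3.0]))
            assert 0.0 < p < 1.0

    def test_shape_mismatch_rejected(self):
        weights = init_sequential_weights(3, seed=1)
        with pytest.raises(ValueError):
            sequential_forward(weights, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            sequential_forward(weights[:-1], np.array([1.0, 2.0, 3.0]))

    def test_training_separates_strong_signal(self):
        rng = np.random.default_rng(5)
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([
            y + rng.normal(0, 0.1, n),
            1 - y + rng.normal(0, 0.1, n),
        ])
        net = SequentialNet(epochs=100, seed=0).fit(X, y.astype(int))
        acc = ((net.predict_proba_rows(X) >= 0.5).astype(int) == y).mean()
        assert acc >= 0.95

    def test_loss_trend_decreases(self):
        rng = np.random.default_rng(6)
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y + rng.normal(0, 0.3, n)])
        net = SequentialNet(epochs=60, seed=0).fit(X, y.astype(int))
        loss = np.array(net.loss_history_)
        # smoothed monotone trend: mean of first 10 vs last 10 epochs
        assert loss[-10:].mean() < loss[:10].mean()

    def test_same_seed_reproduces_predictions(self):
        table = tiny_numeric_table()
        spec = ClassifierSpec("sequential_nn", {"epochs": 30}, seed=3)
        p1 = fit_model(spec, table).predict_proba(table)
        p2 = fit_model(spec, table).predict_proba(table)
        np.testing.assert_array_equal(p1, p2)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            SequentialNet(epochs=1).fit(np.zeros((4, 2)), np.array([0, 1, 2, 1]))


class TestForestAndBank:
    def test_forest_with_one_tree_equals_random_tree(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(50, 6)).astype(float)
        y = (X[:, 0] == 1).astype(int)
        tree = RandomTree(seed=11).fit(X, y)
        forest = RandomForest(n_trees=1, seed=11, bootstrap=False).fit(X, y)
        np.testing.assert_array_equal(
            tree.predict_proba_rows(X), forest.predict_proba_rows(X)
        )

    @pytest.mark.parametrize("name", [
        "naive_bayes", "random_tree", "random_forest", "adaboost_m1",
        "hoeffding_tree", "mlp", "sequential_nn",
    ])
    def test_every_learner_deterministic_given_fit(self, name):
        table = tiny_numeric_table()
        hp = {"epochs": 20} if name == "sequential_nn" else {}
        model = fit_model(ClassifierSpec(name, hp, seed=1), table)
        p1 = model.predict_proba(table)
        p2 = model.predict_proba(table)
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_prediction_refuses_mismatched_columns(self):
        table = tiny_numeric_table()
        model = fit_model(ClassifierSpec("naive_bayes", seed=0), table)
        other = table.select_columns([0, 1])
        with pytest.raises(ValueError, match="column mismatch"):
            model.predict_proba(other)

    def test_unknown_classifier_name_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm")
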