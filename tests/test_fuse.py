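"""Classifier outcomes, iterative majority voting, greedy fusion, metrics."""

import numpy as np
import pytest
from scipy import stats

from gidfe import compute_metrics, greedy_final, imv, knn_outcome, svm_outcome
from gidfe.fuse import Outcome, make_folds


def _brute_force_imv(pred_matrix, accuracies):
    """Independent prefix-mode oracle: sort by accuracy (stable), then for
    each i and each sample take the mode of the top-i predictions with the
    lowest label winning ties."""
    order = np.lexsort((np.arange(len(accuracies)), -np.asarray(accuracies)))
    sorted_preds = pred_matrix[order]
    voted = []
    for i in range(3, len(accuracies) + 1):
        row = []
        for j in range(pred_matrix.shape[1]):
            vals, counts = np.unique(sorted_preds[:i, j], return_counts=True)
            row.append(vals[np.argmax(counts)])  # np.unique sorts ascending
        voted.append(np.array(row))
    return voted


class TestClassifierOutcomes:
    def test_duplicated_labels_give_perfect_knn(self):
        y = np.arange(60) % 3
        out = knn_outcome(y.astype(float)[:, None], y, seed=0)
        assert out.accuracy == 100.0
        assert len(out.predictions) == 60

    def test_well_separated_gaussians_exceed_95_percent(self):
        """Two classes five standard deviations apart are nearly always
        recovered by both classifiers."""
        accs_knn, accs_svm = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.arange(200) % 2
            X = rng.standard_normal((200, 5)) + 5.0 * y[:, None]
            folds = make_folds(y, seed=seed)
            accs_knn.append(knn_outcome(X, y, folds=folds).accuracy)
            accs_svm.append(svm_outcome(X, y, folds=folds).accuracy)
        assert min(accs_knn) > 95.0
        assert min(accs_svm) > 95.0

    def test_linearly_separable_svm_is_perfect(self):
        y = np.arange(40) % 2
        X = np.column_stack([y * 10.0, np.ones(40)])
        assert svm_outcome(X, y, seed=0).accuracy == 100.0

    def test_predictions_are_valid_labels(self, rng):
        y = np.arange(50) % 3
        X = rng.standard_normal((50, 4))
        out = svm_outcome(X, y, seed=0)
        assert set(np.unique(out.predictions)) <= {0, 1, 2}

    def test_shared_folds_give_identical_partitions(self):
        """kNN and SVM judged on the same folds see the same split."""
        y = np.arange(60) % 2
        f1 = make_folds(y, seed=5)
        f2 = make_folds(y, seed=5)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_zero_distance_neighbor_dominates(self):
        """With duplicated points, the exact-match neighbor decides alone."""
        X = np.array([[0.0], [0.0], [1.0], [1.0], [5.0], [5.0], [6.0], [6.0],
                      [0.5], [5.5], [0.25], [5.25]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 1, 0, 1])
        out = knn_outcome(X, y, seed=0)
        assert out.accuracy == 100.0


class TestIMV:
    def test_hand_worked_prefix_modes(self):
        """Predictions [1,1,2,2,2,1,1,1] by accuracy rank at one sample:
        i=3 -> 1; i=4 -> 2:2 tie -> lowest label 1; i=5 -> 2."""
        y = np.array([1, 1])
        outs = [
            Outcome(predictions=np.array([p, 1]), accuracy=100.0 - t,
                    source=("c", t), kind="classifier")
            for t, p in enumerate([1, 1, 2, 2, 2, 1, 1, 1])
        ]
        voted = imv(outs, y)
        assert len(voted) == 6
        assert [v.predictions[0] for v in voted[:3]] == [1, 1, 2]

    def test_unanimous_outcomes_pass_through(self, rng):
        y = rng.integers(0, 3, 20)
        pred = rng.integers(0, 3, 20)
        outs = [Outcome(predictions=pred.copy(), accuracy=50.0, source=("c", t),
                        kind="classifier") for t in range(8)]
        for v in imv(outs, y):
            np.testing.assert_array_equal(v.predictions, pred)

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        """100 random 8-outcome sets (D <= 50): every voted vector equals an
        independent prefix-mode computation."""
        for trial in range(100):
            d = int(rng.integers(2, 51))
            k = int(rng.integers(2, 5))
            y = rng.integers(0, k, d)
            preds = rng.integers(0, k, (8, d))
            accs = rng.random(8) * 100
            outs = [Outcome(predictions=preds[t], accuracy=float(accs[t]),
                            source=("c", t), kind="classifier") for t in range(8)]
            voted = imv(outs, y)
            oracle = _brute_force_imv(preds, accs)
            assert len(voted) == 6
            for v, o in zip(voted, oracle):
                np.testing.assert_array_equal(v.predictions, o, err_msg=f"trial {trial}")

    def test_tie_rule_matches_matlab_style_mode(self, rng):
        """The lowest-label tie rule is the conventional numeric mode."""
        for _ in range(200):
            vals = rng.integers(0, 4, 6)
            ours = np.bincount(vals).argmax()
            assert ours == stats.mode(vals, keepdims=False).mode

    def test_fewer_than_three_outcomes_rejected(self):
        y = np.zeros(3, dtype=int)
        outs = [Outcome(predictions=np.zeros(3, dtype=int), accuracy=1.0,
                        source=("c", 0), kind="classifier")] * 2
        with pytest.raises(ValueError):
            imv(outs, y)

    def test_voting_improves_over_median_of_weak_learners(self):
        """Independent 60%-accurate outcomes: the full 8-vote beats the
        median single outcome in nearly every replicate."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 300)
            outs = []
            for t in range(8):
                flip = rng.random(300) > 0.6
                pred = np.where(flip, 1 - y, y)
                outs.append(Outcome(predictions=pred,
                                    accuracy=100.0 * float(np.mean(pred == y)),
                                    source=("c", t), kind="classifier"))
            voted = imv(outs, y)
            median_acc = np.median([o.accuracy for o in outs])
            wins += voted[-1].accuracy >= median_acc
        assert wins >= 18


class TestGreedyFinal:
    def _outcomes(self, accs, d=4):
        return [
            Outcome(predictions=np.zeros(d, dtype=int), accuracy=a,
                    source=("c", t), kind="classifier")
            for t, a in enumerate(accs)
        ]

    def test_argmax_selects_the_best(self):
        y = np.zeros(4, dtype=int)
        outs = self._outcomes([50.0, 100.0, 75.0])
        outs[1].predictions = np.zeros(4, dtype=int)
        res = greedy_final(outs, y)
        assert res.winner_index == 1
        assert res.winner.accuracy == 100.0

    def test_first_wins_on_ties(self):
        y = np.zeros(4, dtype=int)
        res = greedy_final(self._outcomes([80.0, 80.0, 80.0]), y)
        assert res.winner_index == 0

    def test_permutation_invariance_of_winning_accuracy(self, rng):
        y = rng.integers(0, 2, 10)
        outs = []
        for t in range(6):
            pred = rng.integers(0, 2, 10)
            outs.append(Outcome(predictions=pred,
                                accuracy=100.0 * float(np.mean(pred == y)),
                                source=("c", t), kind="classifier"))
        base = greedy_final(outs, y).winner.accuracy
        perm = [outs[i] for i in rng.permutation(6)]
        assert greedy_final(perm, y).winner.accuracy == base

    def test_metric_cross_check(self, rng):
        """The winner's stored accuracy equals the metric report's."""
        y = rng.integers(0, 3, 30)
        pred = rng.integers(0, 3, 30)
        outs = [Outcome(predictions=pred, accuracy=100.0 * float(np.mean(pred == y)),
                        source=("c", 0), kind="classifier")] * 3
        res = greedy_final(outs, y)
        assert abs(res.metrics.accuracy - res.winner.accuracy) < 1e-9


class TestMetrics:
    def test_hand_computed_binary_confusion(self):
        """Confusion [[9,1],[2,8]]: accuracy 85%, recalls 0.9/0.8,
        geometric mean 100*sqrt(0.72) ~ 84.85%."""
        y = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 9 + [1] + [0] * 2 + [1] * 8)
        m = compute_metrics(pred, y, n_classes=2)
        assert m.accuracy == pytest.approx(85.0)
        assert m.geometric_mean == pytest.approx(100.0 * np.sqrt(0.72), rel=1e-9)
        np.testing.assert_array_equal(m.confusion, [[9, 1], [2, 8]])

    def test_perfect_predictions(self):
        y = np.arange(12) % 3
        m = compute_metrics(y, y, n_classes=3)
        assert (m.accuracy, m.f1, m.geometric_mean) == (100.0, 100.0, 100.0)
        assert np.trace(m.confusion) == 12

    def test_confusion_sums_to_sample_count(self, rng):
        y = rng.integers(0, 4, 37)
        pred = rng.integers(0, 4, 37)
        m = compute_metrics(pred, y, n_classes=4)
        assert m.confusion.sum() == 37

    def test_absent_class_excluded_from_geometric_mean(self):
        y = np.array([0, 0, 1, 1])  # class 2 never occurs
        pred = np.array([0, 0, 1, 1])
        m = compute_metrics(pred, y, n_classes=3)
        assert m.geometric_mean == pytest.approx(100.0)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 3]), np.array([0, 1]), n_classes=2)
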