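"""Metrics against brute-force oracles: DTW path enumeration, MMD double
sums, Mann-Whitney AUROC, plus the protocols and the harness classifier."""
import numpy as np
import pytest

from ecgdiff.evaluation import (EvalReport, ResidualClassifier1D,
                                authenticity_protocol, dtw_distance,
                                median_heuristic_sigma, mmd_rbf,
                                multilabel_accuracy, multilabel_auroc,
                                quality_protocol, train_classifier)


# ---------------------------------------------------------------- oracles

def _dtw_enumerate(x, y):
    """Minimum cost over all monotone warping paths, by exhaustive search."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, cost):
        cost += (x[i] - y[j]) ** 2
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


def _mmd_double_sum(X, Y, sigma):
    X = X.reshape(len(X), -1)
    Y = Y.reshape(len(Y), -1)
    k = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2 * sigma ** 2))
    n, m = len(X), len(Y)
    sx = sum(k(X[i], X[j]) for i in range(n) for j in range(n) if i != j)
    sy = sum(k(Y[i], Y[j]) for i in range(m) for j in range(m) if i != j)
    sxy = sum(k(X[i], Y[j]) for i in range(n) for j in range(m))
    return sx / (n * (n - 1)) + sy / (m * (m - 1)) - 2 * sxy / (n * m)


def _auroc_pairs(scores, truth):
    """Mann-Whitney pair counting with ties at 1/2, macro over labels."""
    vals = []
    for j in range(truth.shape[1]):
        pos = scores[truth[:, j] == 1, j]
        neg = scores[truth[:, j] == 0, j]
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        vals.append(wins / (len(pos) * len(neg)))
    return np.mean(vals)


# ------------------------------------------------------------------ tests

class TestDTW:
    def test_identical_series_zero(self, rng):
        x = rng.standard_normal(20)
        assert dtw_distance(x, x) == 0.0

    def test_single_cell(self):
        assert dtw_distance([0.0], [3.0]) == 9.0

    def test_three_point_example(self):
        # minimum warped cost over the 3x3 grid
        assert dtw_distance([1, 2, 3], [2, 3, 4]) == 2.0

    def test_matches_enumeration_on_random_integer_series(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, m = rng.integers(1, 9, size=2)
            x = rng.integers(-5, 6, size=n).astype(float)
            y = rng.integers(-5, 6, size=m).astype(float)
            assert dtw_distance(x, y) == _dtw_enumerate(x, y)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestMMD:
    def test_point_mass_zero(self):
        X = np.tile([2.0, -1.0], (5, 1))
        assert mmd_rbf(X, X.copy(), sigma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        X = rng.standard_normal((6, 4))
        Y = rng.standard_normal((9, 4))
        assert mmd_rbf(X, Y, 1.3) == pytest.approx(mmd_rbf(Y, X, 1.3),
                                                   abs=1e-12)

    def test_two_point_example(self):
        # X = {0, 1}, Y = {0, 2}, sigma = 1: explicit sums
        X = np.array([[0.0], [1.0]])
        Y = np.array([[0.0], [2.0]])
        e = np.exp
        expected = (2 * e(-0.5) / 2 + 2 * e(-2.0) / 2
                    - 2 / 4 * (1 + e(-2) + e(-0.5) + e(-0.5)))
        assert mmd_rbf(X, Y, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_matches_double_sum(self, rng):
        for _ in range(10):
            n, m = rng.integers(2, 21, size=2)
            X = rng.standard_normal((n, 3))
            Y = rng.standard_normal((m, 3)) + 0.5
            sigma = float(rng.uniform(0.5, 3.0))
            assert mmd_rbf(X, Y, sigma) == pytest.approx(
                _mmd_double_sum(X, Y, sigma), abs=1e-12)

    def test_same_distribution_tends_to_zero(self):
        rng = np.random.default_rng(5)
        vals = []
        for n in (10, 40, 160):
            X = rng.standard_normal((n, 2))
            Y = rng.standard_normal((n, 2))
            vals.append(abs(mmd_rbf(X, Y, 1.0)))
        assert vals[2] < vals[0]

    def test_small_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            mmd_rbf(rng.standard_normal((1, 2)), rng.standard_normal((5, 2)),
                    1.0)
        with pytest.raises(ValueError):
            mmd_rbf(rng.standard_normal((5, 2)), rng.standard_normal((5, 2)),
                    0.0)


class TestMultilabelAccuracy:
    def test_perfect_and_inverted(self, rng):
        truth = (rng.random((5, 4)) < 0.5).astype(float)
        assert multilabel_accuracy(truth, truth) == 1.0
        assert multilabel_accuracy(1 - truth, truth) == 0.0

    def test_partial_ratio(self):
        truth = np.zeros((3, 4))
        pred = np.zeros((3, 4))
        pred[0, 0] = pred[1, 2] = 1  # 2 wrong of 12
        assert multilabel_accuracy(pred, truth) == pytest.approx(10 / 12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            multilabel_accuracy(np.zeros((2, 3)), np.zeros((3, 2)))


class TestMultilabelAuroc:
    def test_perfect_ordering(self, rng):
        truth = np.tile([1, 0, 1, 0], (2, 1)).T.astype(float)
        scores = np.where(truth == 1, 0.9, 0.1) + rng.random((4, 2)) * 0.05
        assert multilabel_auroc(scores, truth) == 1.0

    def test_all_ties_half(self):
        truth = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        scores = np.full((4, 2), 0.5)
        assert multilabel_auroc(scores, truth) == 0.5

    def test_hand_built_table(self):
        truth = np.array([[1, 0], [1, 1], [0, 0], [0, 1], [1, 0], [0, 1]],
                         dtype=float)
        scores = np.array([[0.9, 0.2], [0.6, 0.6], [0.7, 0.3], [0.2, 0.6],
                           [0.5, 0.1], [0.4, 0.9]])
        assert multilabel_auroc(scores, truth) == pytest.approx(
            _auroc_pairs(scores, truth), abs=1e-12)

    def test_matches_pair_counting_random_tables(self):
        rng = np.random.default_rng(9)
        done = 0
        while done < 20:
            n = int(rng.integers(3, 13))
            truth = (rng.random((n, 3)) < 0.5).astype(float)
            if np.any(truth.min(0) == truth.max(0)):
                continue  # avoid degenerate columns for the plain comparison
            scores = np.round(rng.random((n, 3)), 1)  # induce ties
            assert multilabel_auroc(scores, truth) == pytest.approx(
                _auroc_pairs(scores, truth), abs=1e-12)
            done += 1

    def test_degenerate_column_skipped_and_reported(self):
        truth = np.array([[1, 1], [0, 1], [1, 1]], dtype=float)
        scores = np.array([[0.8, 0.5], [0.1, 0.5], [0.7, 0.5]])
        macro, skipped = multilabel_auroc(scores, truth, return_skipped=True)
        assert skipped == [1] and macro == 1.0

    def test_all_degenerate_raises(self):
        with pytest.raises(ValueError):
            multilabel_auroc(np.zeros((3, 2)), np.ones((3, 2)))


class TestQualityProtocol:
    def test_self_comparison_zero_dtw(self, rng):
        recs = rng.standard_normal((6, 2, 16))
        rep = quality_protocol(recs, recs.copy(), batch_size=4)
        assert rep.avg_dtw == 0.0
        assert rep.batch_size == 4

    def test_default_batch_size_16(self, rng):
        recs = rng.standard_normal((4, 1, 8))
        assert quality_protocol(recs, recs).batch_size == 16

    def test_batched_equals_unbatched(self, rng):
        real = rng.standard_normal((10, 2, 12))
        gen = rng.standard_normal((10, 2, 12))
        a = quality_protocol(real, gen, batch_size=3, sigma=1.0)
        b = quality_protocol(real, gen, batch_size=1000, sigma=1.0)
        assert a.avg_dtw == pytest.approx(b.avg_dtw, abs=1e-9)
        assert a.mmd == pytest.approx(b.mmd, abs=1e-12)

    def test_matches_naive_recomputation(self, rng):
        real = rng.standard_normal((5, 2, 10))
        gen = rng.standard_normal((5, 2, 10))
        rep = quality_protocol(real, gen, sigma=2.0)
        naive = np.mean([
            np.mean([dtw_distance(real[i, c], gen[i, c]) for c in range(2)])
            for i in range(5)])
        assert rep.avg_dtw == pytest.approx(naive, abs=1e-9)
        assert rep.mmd == pytest.approx(_mmd_double_sum(real, gen, 2.0),
                                        abs=1e-12)

    def test_concat_mode(self, rng):
        real = rng.standard_normal((3, 2, 6))
        gen = rng.standard_normal((3, 2, 6))
        rep = quality_protocol(real, gen, dtw_mode="concat", sigma=1.0)
        naive = np.mean([dtw_distance(real[i].ravel(), gen[i].ravel())
                         for i in range(3)])
        assert rep.avg_dtw == pytest.approx(naive, abs=1e-9)

    def test_label_matched_pairing(self, rng):
        real = rng.standard_normal((4, 1, 6))
        labels = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        # same records shuffled; within-label order preserved
        perm = [1, 0, 3, 2]
        rep = quality_protocol(real, real[perm], labels_real=labels,
                               labels_generated=labels[perm], sigma=1.0)
        assert rep.avg_dtw == 0.0  # pairing matches identical records

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quality_protocol(np.empty((0, 1, 4)), np.empty((0, 1, 4)))


class TestAuthenticityProtocol:
    def _data(self, rng, n=24):
        x = rng.standard_normal((n, 2, 16))
        y = (rng.random((n, 2)) < 0.5).astype(float)
        y[0] = [1, 0]
        y[1] = [0, 1]  # ensure non-degenerate columns
        return x, y

    def test_identical_sets_zero_gaps(self, rng):
        clf = ResidualClassifier1D(2, 2, seed=0)
        x, y = self._data(rng)
        rep = authenticity_protocol(clf, (x, y), (x.copy(), y.copy()))
        assert rep.accuracy_gap == 0.0
        assert rep.auroc_gap == 0.0

    def test_random_classifier_near_half_auroc(self):
        rng = np.random.default_rng(1)
        clf = ResidualClassifier1D(2, 2, seed=3)
        x, y = self._data(rng, n=400)
        x2, y2 = self._data(rng, n=400)
        rep = authenticity_protocol(clf, (x, y), (x2, y2))
        # scores are label-independent -> AUROC concentrates near 0.5
        assert abs(rep.auroc_real - 0.5) < 0.15
        assert abs(rep.auroc_generated - 0.5) < 0.15

    def test_label_space_mismatch(self, rng):
        clf = ResidualClassifier1D(2, 2, seed=0)
        x, y = self._data(rng)
        with pytest.raises(ValueError):
            authenticity_protocol(clf, (x, y), (x, y[:, :1]))


class TestClassifier:
    def test_training_learns_separable_labels(self):
        from ecgdiff.synth import generate_dataset, two_class_config
        cfg = two_class_config(200, seed=3)
        records, labels = generate_dataset(cfg)
        clf = ResidualClassifier1D(2, 2, width=12, depth=1, seed=1)
        losses = train_classifier(clf, records, labels, steps=150, lr=2e-2,
                                  batch_size=32, seed=2)
        assert losses[-1] < losses[0]
        scores = clf.predict_scores(records)
        auroc = multilabel_auroc(scores, labels)
        assert auroc > 0.9

    def test_report_serialization(self):
        rep = EvalReport(avg_dtw=1.0, mmd=0.5)
        text = rep.to_text()
        assert "avg_dtw\t1.0" in text
        assert rep.to_dict()["mmd"] == 0.5
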