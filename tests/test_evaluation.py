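import itertools
import math

import numpy as np
import pytest

from deephistoclass.errors import ConfigError, DataError
from deephistoclass.evaluation import (average_precision, evaluate,
                                       exact_match, f1_scores,
                                       grid_search_thresholds, hamming_loss,
                                       kendall_label_correlation, mcc,
                                       mean_average_precision)


from _oracles import bf_ap, bf_exact, bf_f1, bf_hamming


def bf_kendall_tau_b(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1; ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom


class TestHammingLoss:
    def test_identical_zero(self, label_matrix):
        assert hamming_loss(label_matrix, label_matrix) == 0.0

    def test_complement_one(self, label_matrix):
        assert hamming_loss(label_matrix, 1 - label_matrix) == 1.0

    def test_hand_example(self):
        assert hamming_loss([[1, 0], [0, 1]], [[1, 1], [0, 1]]) == 0.25

    def test_shape_mismatch(self):
        with pytest.raises(ConfigError):
            hamming_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestF1:
    def test_perfect(self, label_matrix):
        assert f1_scores(label_matrix, label_matrix) == (1.0, 1.0)

    def test_half_macro(self):
        Yt = np.array([[1, 1], [1, 0], [0, 1]])
        Yp = np.array([[1, 0], [1, 1], [0, 0]])  # label 0 perfect, label 1 all wrong
        macro, _ = f1_scores(Yt, Yp)
        assert macro == pytest.approx(0.5)


class TestExactMatch:
    def test_perfect(self, label_matrix):
        assert exact_match(label_matrix, label_matrix) == 1.0

    def test_two_of_three(self):
        Yt = np.array([[1, 0], [0, 1], [1, 1]])
        Yp = np.array([[1, 0], [0, 1], [0, 1]])
        assert exact_match(Yt, Yp) == pytest.approx(2 / 3)

    def test_bounded_by_per_label_accuracy(self, rng):
        Yt = rng.integers(0, 2, (20, 4))
        Yp = rng.integers(0, 2, (20, 4))
        per_label_acc = (Yt == Yp).mean(axis=0)
        assert exact_match(Yt, Yp) <= per_label_acc.min() + 1e-12


class TestAveragePrecision:
    def test_hand_example(self):
        assert average_precision([1, 0, 1], [0.9, 0.8, 0.7]) == pytest.approx(
            (1 + 2 / 3) / 2)

    def test_perfect_ranking(self, rng):
        y = np.array([1] * 5 + [0] * 10)
        s = -np.arange(15, dtype=float)
        assert average_precision(y, s) == 1.0

    def test_random_scores_near_prevalence(self, rng):
        aps = []
        for _ in range(100):
            y = (rng.random(200) < 0.3).astype(int)
            if y.sum() == 0:
                continue
            aps.append(average_precision(y, rng.random(200)))
        assert 0.2 < np.mean(aps) < 0.45

    def test_no_positives_error(self):
        with pytest.raises(DataError):
            mean_average_precision(np.zeros((5, 2), dtype=int),
                                   np.random.default_rng(0).random((5, 2)))


class TestBruteForceAgreement:
    """All metrics against exhaustive per-cell tallies on random instances."""

    def test_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 9))
            C = int(rng.integers(1, 5))
            Yt = rng.integers(0, 2, (n, C))
            Yp = rng.integers(0, 2, (n, C))
            assert hamming_loss(Yt, Yp) == pytest.approx(bf_hamming(Yt, Yp))
            assert exact_match(Yt, Yp) == pytest.approx(bf_exact(Yt, Yp))
            macro, micro = f1_scores(Yt, Yp)
            bfm, bfmi = bf_f1(Yt, Yp)
            assert macro == pytest.approx(bfm)
            assert micro == pytest.approx(bfmi)
            S = rng.random((n, C))
            for c in range(C):
                if Yt[:, c].sum():
                    assert average_precision(Yt[:, c], S[:, c]) == \
                        pytest.approx(bf_ap(Yt[:, c], S[:, c]))

    def test_row_permutation_invariance(self, rng):
        Yt = rng.integers(0, 2, (12, 3))
        Yp = rng.integers(0, 2, (12, 3))
        perm = rng.permutation(12)
        assert hamming_loss(Yt, Yp) == hamming_loss(Yt[perm], Yp[perm])
        assert exact_match(Yt, Yp) == exact_match(Yt[perm], Yp[perm])
        assert f1_scores(Yt, Yp) == f1_scores(Yt[perm], Yp[perm])


class TestMCC:
    def test_closed_form_example(self):
        assert mcc(2, 1, 0, 2) == pytest.approx((2 * 2 - 1 * 0) /
                                                math.sqrt(3 * 2 * 3 * 2))

    def test_zero_denominator_convention(self):
        assert mcc(0, 0, 3, 5) == 0.0

    def test_range(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 10, 4)
            assert -1.0 - 1e-12 <= mcc(tp, fp, fn, tn) <= 1.0 + 1e-12

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            tp = int(((y == 1) & (p == 1)).sum())
            fp = int(((y == 0) & (p == 1)).sum())
            fn = int(((y == 1) & (p == 0)).sum())
            tn = int(((y == 0) & (p == 0)).sum())
            assert mcc(tp, fp, fn, tn) == pytest.approx(
                matthews_corrcoef(y, p), abs=1e-12)


class TestThresholdSearch:
    def test_separable_scores_reach_mcc_one(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        s = np.concatenate([rng.uniform(0.05, 0.35, 10),
                            rng.uniform(0.65, 0.95, 10)])
        ts = grid_search_thresholds(y[:, None], s[:, None])
        assert ts.mcc_values[0] == pytest.approx(1.0)
        assert s[:10].max() < ts.prob_thresholds[0] <= s[10:].min()

    def test_two_gaussian_recovers_midpoint(self, rng):
        n = 2000
        y = rng.integers(0, 2, (n, 8))
        s = np.clip(np.where(y == 1, rng.normal(0.7, 0.1, (n, 8)),
                             rng.normal(0.3, 0.1, (n, 8))), 0, 1)
        ts = grid_search_thresholds(y, s)
        assert np.all(np.abs(ts.prob_thresholds - 0.5) <= 0.05)

    def test_ties_take_lowest_threshold(self):
        y = np.array([[0], [1]])
        s = np.array([[0.2], [0.8]])
        ts = grid_search_thresholds(y, s, grid=[0.3, 0.5, 0.7])
        assert ts.prob_thresholds[0] == 0.3

    def test_invalid_grid(self):
        with pytest.raises(ConfigError):
            grid_search_thresholds(np.zeros((2, 1)), np.zeros((2, 1)), grid=[])


class TestKendall:
    def test_duplicated_column_perfectly_concordant(self, rng):
        x = rng.integers(0, 4, 20)
        M = np.column_stack([x, x])
        K = kendall_label_correlation(M)
        assert K[0, 1] == pytest.approx(1.0)

    def test_reversed_column_discordant(self):
        x = np.arange(10)
        K = kendall_label_correlation(np.column_stack([x, x[::-1]]))
        assert K[0, 1] == pytest.approx(-1.0)

    def test_hand_example_matches_pair_count_oracle(self, rng):
        M = rng.integers(0, 4, (5, 3))
        while any(np.all(M[:, c] == M[0, c]) for c in range(3)):
            M = rng.integers(0, 4, (5, 3))
        K = kendall_label_correlation(M)
        for a in range(3):
            for b in range(a + 1, 3):
                assert K[a, b] == pytest.approx(
                    bf_kendall_tau_b(M[:, a], M[:, b]), abs=1e-12)

    def test_constant_column_zero_with_warning(self):
        M = np.column_stack([np.arange(6), np.full(6, 2)])
        with pytest.warns(UserWarning):
            K = kendall_label_correlation(M)
        assert K[0, 1] == 0.0
        assert np.all(np.diag(K) == 1.0)


class TestEvaluate:
    def test_report_consistency(self, rng):
        Yt = rng.integers(0, 2, (40, 8))
        Yp = rng.integers(0, 2, (40, 8))
        S = rng.random((40, 8))
        rep = evaluate(Yt, Yp, scores=S)
        assert rep.n_images == 40
        counts = rep.per_label[["tp", "fp", "fn", "tn"]].sum(axis=1)
        assert (counts == 40).all()
        assert rep.exact_match <= rep.per_label["accuracy"].min() + 1e-12
        assert "Hamming" in rep.summary()
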