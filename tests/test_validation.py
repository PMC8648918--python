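"""Hold-out / k-fold drivers, permutation test, Cochran's Q, McNemar and
Bonferroni — with statsmodels and closed-form binomial oracles."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from mgmdhafs.data import FeatureTable
from mgmdhafs.validation import (bonferroni, cochran_q, correctness_matrix,
                                 evaluate_holdout, evaluate_kfold, mcnemar,
                                 permutation_test)
from conftest import make_labels


# -- simple deterministic trainers for the drivers --------------------------

class _ThresholdResults:
    def __init__(self, flip=False):
        self.flip = flip

    def predict(self, table):
        p = (table.values[:, 0] > 0).astype(int)
        return 1 - p if self.flip else p

    def predict_scores(self, table):
        s = table.values[:, 0]
        return -s if self.flip else s


def oracle_trainer(table, labels, seed):
    """Memorizes the noiseless rule y = 1[x1 > 0]."""
    return _ThresholdResults()


class _ConstantResults:
    def predict(self, table):
        return np.zeros(table.n_samples, dtype=int)

    def predict_scores(self, table):
        return np.zeros(table.n_samples)


def constant_majority_trainer(table, labels, seed):
    return _ConstantResults()


def signal_dataset(n_pos=20, n_neg=80, seed=0):
    rng = np.random.default_rng(seed)
    y = make_labels(n_pos, n_neg)
    x = np.where(y == 1, 1.0, -1.0) + rng.normal(scale=0.01, size=len(y))
    table = FeatureTable([f"s{i}" for i in range(len(y))], ["x1"],
                         x.reshape(-1, 1), ["continuous"])
    return table, y


class TestEvaluateHoldout:
    def test_oracle_trainer_is_perfect(self):
        table, y = signal_dataset()
        hr = evaluate_holdout(oracle_trainer, table, y, 0.7, seed=0)
        assert hr.metrics.accuracy == 1.0 and hr.metrics.auc == 1.0

    def test_constant_majority_arithmetic(self):
        table, y = signal_dataset(n_pos=10, n_neg=90)
        hr = evaluate_holdout(constant_majority_trainer, table, y, 0.7, seed=0)
        assert hr.metrics.sensitivity == 0.0
        assert hr.metrics.specificity == 1.0
        assert hr.metrics.accuracy == pytest.approx(0.9)

    def test_same_seed_identical_metrics(self):
        table, y = signal_dataset()
        a = evaluate_holdout(oracle_trainer, table, y, 0.7, seed=5)
        b = evaluate_holdout(oracle_trainer, table, y, 0.7, seed=5)
        assert a.metrics.as_dict() == b.metrics.as_dict()
        assert np.array_equal(a.test_indices, b.test_indices)


class TestEvaluateKfold:
    def test_oracle_pooled_accuracy(self):
        table, y = signal_dataset()
        kr = evaluate_kfold(oracle_trainer, table, y, k=4, seed=0)
        assert kr.pooled.accuracy == 1.0

    def test_pooled_counts_are_sum_of_fold_counts(self):
        table, y = signal_dataset(seed=3)
        kr = evaluate_kfold(constant_majority_trainer, table, y, k=4, seed=1)
        summed = [sum(m.counts.tp for m in kr.per_fold),
                  sum(m.counts.fp for m in kr.per_fold),
                  sum(m.counts.tn for m in kr.per_fold),
                  sum(m.counts.fn for m in kr.per_fold)]
        pooled = kr.pooled.counts
        assert summed == [pooled.tp, pooled.fp, pooled.tn, pooled.fn]

    def test_constant_majority_pooled_accuracy_matches_prevalence(self):
        table, y = signal_dataset(n_pos=10, n_neg=90)
        kr = evaluate_kfold(constant_majority_trainer, table, y, k=4, seed=0)
        assert kr.pooled.accuracy == pytest.approx(0.9)


class TestPermutationTest:
    def test_report_length_matches_requested_permutations(self):
        table, y = signal_dataset()
        report = permutation_test(oracle_trainer, table, y, n_permutations=10, seed=0)
        assert len(report.permuted) == 10

    def test_oracle_mcc_beats_every_permutation(self):
        table, y = signal_dataset()
        report = permutation_test(oracle_trainer, table, y, n_permutations=10, seed=0)
        assert report.p_values["mcc"] == pytest.approx(1 / 11)

    def test_empirical_p_never_zero_and_at_most_one(self):
        table, y = signal_dataset()
        report = permutation_test(constant_majority_trainer, table, y,
                                  n_permutations=5, seed=2)
        for p in report.p_values.values():
            if p is not None:
                assert 0 < p <= 1

    def test_permutations_preserve_class_ratio(self):
        table, y = signal_dataset()
        report = permutation_test(oracle_trainer, table, y, n_permutations=5, seed=1)
        for m in report.permuted:
            counts = m.counts
            assert counts.tp + counts.fn == int(np.sum(y[  # same positives in test
                evaluate_holdout(oracle_trainer, table, y, 0.7, 1).test_indices]))


class TestCochranQ:
    def test_identical_classifiers_give_zero_with_flag(self):
        col = np.array([1, 0, 1, 1, 0])
        res = cochran_q(np.column_stack([col, col]))
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.undefined

    def test_k2_equals_uncorrected_mcnemar_statistic(self, rng):
        for _ in range(100):
            M = rng.integers(0, 2, size=(30, 2))
            res = cochran_q(M)
            b = int(np.sum((M[:, 0] == 1) & (M[:, 1] == 0)))
            c = int(np.sum((M[:, 0] == 0) & (M[:, 1] == 1)))
            if b + c == 0:
                assert res.undefined
            else:
                assert res.statistic == pytest.approx((b - c) ** 2 / (b + c))

    def test_all_rows_correct_is_degenerate(self):
        res = cochran_q(np.ones((6, 3), dtype=int))
        assert res.undefined and res.p_value == 1.0

    def test_invariance_under_row_and_column_permutation(self, rng):
        M = rng.integers(0, 2, size=(40, 4))
        base = cochran_q(M)
        rows = rng.permutation(40)
        cols = rng.permutation(4)
        permuted = cochran_q(M[rows][:, cols])
        assert permuted.statistic == pytest.approx(base.statistic)
        assert permuted.p_value == pytest.approx(base.p_value)


class TestMcnemar:
    def _vectors(self, b, c, both=30):
        a_correct = np.r_[np.ones(both), np.ones(b), np.zeros(c)].astype(int)
        b_correct = np.r_[np.ones(both), np.zeros(b), np.ones(c)].astype(int)
        return a_correct, b_correct

    def test_symmetric_discordance_has_p_one(self):
        res = mcnemar(*self._vectors(10, 10))
        assert res.p_value == 1.0 and res.exact

    def test_exact_binomial_tail_example(self):
        res = mcnemar(*self._vectors(15, 5))
        expected = 2 * sum(stats.binom.pmf(i, 20, 0.5) for i in range(6))
        assert res.p_value == pytest.approx(expected, abs=1e-9)
        assert res.p_value == pytest.approx(0.0413894653, abs=1e-6)

    def test_chi_square_branch_example(self):
        res = mcnemar(*self._vectors(100, 60))
        assert res.statistic == pytest.approx(39 ** 2 / 160)
        assert res.p_value == pytest.approx(stats.chi2.sf(39 ** 2 / 160, 1), abs=1e-9)
        assert not res.exact

    def test_no_discordance(self):
        res = mcnemar(*self._vectors(0, 0))
        assert res.p_value == 1.0 and res.statistic == 0.0

    @pytest.mark.parametrize("b,c", [(8, 3), (12, 12), (5, 19)])
    def test_exact_branch_matches_statsmodels(self, b, c):
        a_vec, b_vec = self._vectors(b, c)
        table = [[int(np.sum((a_vec == 1) & (b_vec == 1))), b], [c, 0]]
        ours = mcnemar(a_vec, b_vec)
        ref = sm_mcnemar(np.array(table), exact=True)
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_exact_and_approximate_agree_asymptotically(self):
        for n, b in ((200, 110), (200, 90), (300, 160)):
            c = n - b
            approx = mcnemar(*self._vectors(b, c)).p_value
            exact = min(1.0, 2 * stats.binom.cdf(min(b, c), n, 0.5))
            assert abs(approx - exact) < 0.01

    def test_type_one_error_calibration(self, rng):
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a_corr = rng.uniform(size=100) < 0.8
            b_corr = rng.uniform(size=100) < 0.8
            if mcnemar(a_corr.astype(int), b_corr.astype(int)).p_value < 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.07


class TestBonferroni:
    @pytest.mark.parametrize("pvals,m,expected", [
        ([0.01], 5, [0.05]),
        ([0.4], 5, [1.0]),
        ([0.02, 0.03, 0.04], None, [0.06, 0.09, 0.12]),
    ])
    def test_adjustment(self, pvals, m, expected):
        assert bonferroni(pvals, m) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


def test_correctness_matrix_shape_and_order():
    y = np.array([1, 0, 1, 0])
    preds = {"a": [1, 0, 0, 0], "b": [1, 1, 1, 0]}
    M, names = correctness_matrix(y, preds)
    assert names == ["a", "b"]
    assert M.tolist() == [[1, 1], [1, 0], [0, 1], [1, 1]]
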