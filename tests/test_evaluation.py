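"""Metric implementations against independent oracles."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mciprog.errors import ComparisonError, UndefinedMetricError
from mciprog.evaluation import (MetricReport, auc, bootstrap_ci,
                                compare_models, mann_whitney_test, mcc,
                                r_squared)
import pandas as pd


def brute_force_auc(scores, labels):
    """Exhaustive pair enumeration, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_mwu_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = np.delete(pooled, list(idx_a))
        return sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in aa for y in bb)

    observed = u_stat(range(n_a))
    n_total = len(pooled)
    us = [u_stat(c) for c in
          itertools.combinations(range(n_total), n_a)]
    mean_u = n_a * (n_total - n_a) / 2.0
    dev = abs(observed - mean_u)
    extreme = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12)
    return extreme / len(us)


class TestAuc:
    def test_separation_extremes(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]) == 0.0

    def test_matches_pair_counting_oracle_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            labels = rng.integers(0, 2, n)
            while labels.min() == labels.max():
                labels = rng.integers(0, 2, n)
            scores = np.round(rng.random(n), 2)   # provoke ties
            ours = auc(scores, labels)
            assert ours == pytest.approx(brute_force_auc(scores, labels),
                                         abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores),
                                         abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.4, 0.6], [1, 1])


class TestMcc:
    def test_perfect_predictions(self):
        assert mcc([1, 0, 1, 0], [1, 0, 1, 0], threshold=None) == 1.0

    def test_direct_formula_on_toy_confusion_matrix(self):
        # TP=6, TN=3, FP=1, FN=2 -> 16 / sqrt(1120)
        y_true = [1] * 6 + [0] * 3 + [0] * 1 + [1] * 2
        y_pred = [1] * 6 + [0] * 3 + [1] * 1 + [0] * 2
        assert mcc(y_pred, y_true, threshold=None) == pytest.approx(
            16.0 / np.sqrt(1120.0), abs=1e-12)

    def test_zero_marginal_convention(self):
        assert mcc([1, 1, 1], [1, 0, 1], threshold=None) == 0.0

    def test_probability_thresholding(self):
        assert mcc([0.9, 0.4, 0.8, 0.1], [1, 0, 1, 0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(UndefinedMetricError):
            mcc([], [])


class TestR2:
    def test_identity_and_null_model(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(t, t) == 1.0
        assert r_squared(np.full(4, t.mean()), t) == 0.0

    def test_negative_for_anticorrelated_predictions(self):
        t = np.array([1.0, 2.0, 3.0])
        p = np.array([3.0, 2.0, 1.0])
        ss_res = np.sum((t - p) ** 2)
        ss_tot = np.sum((t - t.mean()) ** 2)
        expected = 1 - ss_res / ss_tot
        assert expected < 0
        assert r_squared(p, t) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            r_squared(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        u, p, sig = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)
        assert not sig

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 6)))
            b = rng.normal(size=int(rng.integers(3, 6)))
            _, p, _ = mann_whitney_test(a, b)
            assert p == pytest.approx(enumerate_mwu_p(a, b), abs=1e-9)

    def test_identical_samples_and_symmetry(self, rng):
        a = [0.3, 0.5, 0.7, 0.9]
        _, p_self, sig = mann_whitney_test(a, a)
        assert p_self >= 0.99 and not sig
        b = list(rng.normal(size=12))
        c = list(rng.normal(size=9))
        assert mann_whitney_test(b, c)[1] == pytest.approx(
            mann_whitney_test(c, b)[1], abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(UndefinedMetricError):
            mann_whitney_test([], [1.0])


class TestBootstrap:
    def test_constant_metric_gives_zero_width(self):
        lo, hi = bootstrap_ci(lambda s, l: 0.42, np.arange(10.0),
                              np.ones(10), reps=200, seed=0)
        assert lo == hi == 0.42

    def test_interval_contains_point_estimate(self, rng):
        for trial in range(20):
            n = 60
            labels = rng.integers(0, 2, n)
            while labels.min() == labels.max():
                labels = rng.integers(0, 2, n)
            scores = rng.random(n) + 0.3 * labels
            point = auc(scores, labels)
            lo, hi = bootstrap_ci(auc, scores, labels, reps=2000,
                                  seed=trial)
            assert lo <= point <= hi

    def test_determinism_and_reps_guard(self):
        scores = np.random.default_rng(3).random(40)
        labels = np.random.default_rng(4).integers(0, 2, 40)
        a = bootstrap_ci(auc, scores, labels, reps=300, seed=9)
        b = bootstrap_ci(auc, scores, labels, reps=300, seed=9)
        assert a == b
        with pytest.raises(UndefinedMetricError):
            bootstrap_ci(auc, scores, labels, reps=10, seed=0)


def _report(name, values, sig="plan"):
    df = pd.DataFrame({
        "outer_fold": np.repeat(np.arange(1, 6), 10),
        "inner_fold": np.tile(np.arange(1, 11), 5),
        "metric": "auc", "value": values})
    return MetricReport(model=name, task="progression", fold_values=df,
                        plan_signature=sig)


class TestCompareModels:
    def test_self_comparison_not_significant(self, rng):
        vals = rng.random(50)
        m = compare_models([_report("a", vals), _report("b", vals)], "auc")
        assert m.loc["a", "b"] >= 0.99

    def test_constant_shift_is_significant_and_symmetric(self, rng):
        vals = rng.random(50) * 0.1 + 0.6
        m = compare_models([_report("a", vals),
                            _report("b", vals + 0.2)], "auc")
        assert m.loc["a", "b"] < 1e-6
        assert m.loc["a", "b"] == m.loc["b", "a"]

    def test_mismatched_plans_rejected(self, rng):
        with pytest.raises(ComparisonError):
            compare_models([_report("a", rng.random(50), "p1"),
                            _report("b", rng.random(50), "p2")], "auc")


def test_outer_fold_means_equal_inner_metric_means(rng):
    rep = _report("m", rng.random(50))
    means = rep.outer_means("auc")
    df = rep.fold_values
    for f in range(1, 6):
        manual = df[df["outer_fold"] == f]["value"].mean()
        assert means.loc[f] == pytest.approx(manual, abs=1e-12)
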