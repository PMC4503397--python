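"""Metrics, predictor comparison, and the non-binder RPP analysis."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from nabind.evaluation import (ComparisonReport, ConfusionCounts, KsReport,
                               auc, chain_based_evaluation,
                               compare_predictors, compare_rpp_distributions,
                               metrics_from_counts, residue_based_evaluation,
                               residue_metrics, rpp)
from nabind.hybrid import PredictionResult
from nabind.io_formats import DataError


def mcc_oracle(tp, fp, fn, tn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def auc_oracle(scores, labels):
    """All-pairs counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestResidueMetrics:
    def test_perfect_prediction(self):
        y = np.array([True, False, True, False])
        s = np.array([0.9, 0.1, 0.8, 0.2])
        ms = residue_metrics(s, s >= 0.5, y)
        assert (ms.recall, ms.precision, ms.f1, ms.acc, ms.mcc, ms.auc) == \
            (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_against_formula_oracle(self):
        c = ConfusionCounts(tp=6, fp=4, fn=2, tn=88)
        ms = metrics_from_counts(c)
        assert ms.precision == pytest.approx(0.6)
        assert ms.recall == pytest.approx(0.75)
        assert ms.mcc == pytest.approx(mcc_oracle(6, 4, 2, 88), abs=1e-12)

    def test_all_negative_calls(self):
        y = np.array([True, False, False])
        s = np.array([0.1, 0.1, 0.1])
        ms = residue_metrics(s, np.zeros(3, bool), y)
        assert ms.recall == 0.0
        assert ms.precision == 0.0  # undefined -> 0 by convention
        assert ms.mcc == 0.0 and not ms.mcc_defined

    def test_random_tables_match_oracle_and_sklearn(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(0, 50, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            ms = metrics_from_counts(ConfusionCounts(int(tp), int(fp),
                                                     int(fn), int(tn)))
            assert ms.mcc == pytest.approx(mcc_oracle(tp, fp, fn, tn),
                                           abs=1e-12)
            y = np.array([True] * tp + [False] * fp + [True] * fn
                         + [False] * tn)
            calls = np.array([True] * (tp + fp) + [False] * (fn + tn))
            if len(np.unique(calls)) == 2:
                assert ms.mcc == pytest.approx(matthews_corrcoef(y, calls),
                                               abs=1e-9)

    def test_mcc_swap_invariance_f1_not(self, rng):
        # swapping (TP<->TN, FP<->FN) preserves MCC but generally not F1
        f1_changed = 0
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 50, 4))
            a = metrics_from_counts(ConfusionCounts(tp, fp, fn, tn))
            b = metrics_from_counts(ConfusionCounts(tn, fn, fp, tp))
            assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
            if abs(a.f1 - b.f1) > 1e-9:
                f1_changed += 1
        assert f1_changed > 0


class TestAuc:
    def test_perfect_ranking(self):
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]),
                   np.array([True, True, False, False])) == 1.0

    def test_constant_scores_give_half(self):
        assert auc(np.ones(10), np.arange(10) < 4) == 0.5

    def test_eight_point_fixture_matches_all_pairs_oracle(self):
        scores = np.array([0.9, 0.8, 0.8, 0.6, 0.5, 0.4, 0.4, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0, 1, 0], bool)
        assert auc(scores, labels) == pytest.approx(
            auc_oracle(scores, labels), abs=1e-15)

    def test_random_scores_match_oracle_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            got = auc(scores, labels)
            assert got == pytest.approx(auc_oracle(scores, labels), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.3
        if not labels.any() or labels.all():
            labels[:3] = True
            labels[3:] = False
        transformed = 1.0 / (1.0 + np.exp(-5 * scores))
        assert auc(scores, labels) == pytest.approx(
            auc(transformed, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            auc(np.array([0.1, 0.2]), np.array([True, True]))


def result_from(chain_id, scores, calls=None):
    scores = np.asarray(scores, float)
    calls = scores >= 0.5 if calls is None else np.asarray(calls, bool)
    return PredictionResult(chain_id, "A" * len(scores), scores, None, None,
                            scores, calls)


class TestChainBasedEvaluation:
    def test_mean_of_chain_mccs(self):
        # chain a: MCC known; chain b: different MCC; mean reported
        res = [result_from("a", [0.9, 0.9, 0.1, 0.1]),
               result_from("b", [0.9, 0.1, 0.9, 0.1])]
        labels = {"a": np.array([1, 1, 0, 0], bool),
                  "b": np.array([1, 1, 0, 0], bool)}
        report = chain_based_evaluation(res, labels)
        expected = np.mean([report.per_chain["a"].mcc,
                            report.per_chain["b"].mcc])
        assert report.metrics.mcc == pytest.approx(expected)
        assert report.per_chain["a"].mcc == pytest.approx(1.0)
        assert report.per_chain["b"].mcc == pytest.approx(0.0)

    def test_single_chain_equals_residue_level(self):
        res = [result_from("a", [0.9, 0.4, 0.6, 0.1])]
        labels = {"a": np.array([1, 1, 0, 0], bool)}
        chain = chain_based_evaluation(res, labels)
        residue = residue_based_evaluation(res, labels)
        assert chain.metrics.mcc == pytest.approx(residue.metrics.mcc)
        assert chain.metrics.auc == pytest.approx(residue.metrics.auc)

    def test_pooling_weights_differ_from_chain_mean(self):
        # one perfectly predicted big chain + one at-chance small chain:
        # the chain mean is the midpoint, the pooled value is size-weighted
        big = result_from("big", [0.9] * 10 + [0.1] * 30)
        small = result_from("small", [0.6, 0.6, 0.4, 0.4])
        labels = {"big": np.array([True] * 10 + [False] * 30),
                  "small": np.array([True, False, True, False])}
        chain = chain_based_evaluation([big, small], labels)
        residue = residue_based_evaluation([big, small], labels)
        assert chain.metrics.mcc == pytest.approx(
            (chain.per_chain["big"].mcc + chain.per_chain["small"].mcc) / 2)
        assert residue.metrics.mcc != pytest.approx(chain.metrics.mcc)

    def test_pooling_associativity(self, rng):
        # pooled counts over chains == metrics of the concatenation
        res, labels = [], {}
        all_scores, all_labels = [], []
        for i in range(4):
            n = int(rng.integers(10, 30))
            s = rng.random(n)
            y = rng.random(n) < 0.3
            res.append(result_from(f"c{i}", s))
            labels[f"c{i}"] = y
            all_scores.append(s)
            all_labels.append(y)
        pooled = residue_based_evaluation(res, labels).metrics
        concat = residue_metrics(np.concatenate(all_scores),
                                 np.concatenate(all_scores) >= 0.5,
                                 np.concatenate(all_labels))
        assert pooled.mcc == pytest.approx(concat.mcc, abs=1e-12)
        assert pooled.f1 == pytest.approx(concat.f1, abs=1e-12)
        assert pooled.auc == pytest.approx(concat.auc, abs=1e-12)


class TestComparePredictors:
    def test_identical_vectors_no_difference(self):
        a = np.linspace(0.1, 0.9, 20)
        report = compare_predictors(a, a.copy())
        assert report.test_name == "no-difference"
        assert not report.significant

    def test_gaussian_shift_uses_paired_t(self, rng):
        b = rng.normal(0.5, 0.05, size=50)
        a = b + 0.1 + rng.normal(0, 0.02, size=50)
        report = compare_predictors(a, b)
        assert report.test_name == "paired-t"
        assert report.p_value < 0.05 and report.significant

    def test_heavy_tailed_differences_use_wilcoxon(self):
        # the normality gate should route Cauchy-like differences to the
        # signed-rank test for most seeds
        chosen = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            b = r.normal(0.5, 0.05, size=40)
            a = b + r.standard_cauchy(40) * 0.05
            chosen.append(compare_predictors(a, b).test_name)
        assert chosen.count("wilcoxon-signed-rank") > 5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            compare_predictors(np.ones(3), np.zeros(3))


class TestRpp:
    @pytest.mark.parametrize("calls,expected", [
        ([True] * 10 + [False] * 90, 0.1),
        ([False] * 50, 0.0),
        ([True] * 7, 1.0),
    ])
    def test_ratio(self, calls, expected):
        res = result_from("c", np.zeros(len(calls)), calls)
        assert rpp(res) == pytest.approx(expected)


def ks_oracle(a, b):
    """Max ECDF gap over the pooled sample points."""
    a, b = np.sort(a), np.sort(b)
    pts = np.concatenate([a, b])
    gaps = [abs(np.searchsorted(a, x, "right") / len(a)
                - np.searchsorted(b, x, "right") / len(b)) for x in pts]
    return max(gaps)


class TestCompareRpp:
    def test_identical_samples(self):
        a = np.array([0.1, 0.2, 0.3])
        report = compare_rpp_distributions(a, a.copy())
        assert report.statistic == 0.0

    def test_disjoint_support(self):
        report = compare_rpp_distributions(np.array([0.1, 0.2]),
                                           np.array([0.8, 0.9]))
        assert report.statistic == 1.0

    def test_matches_ecdf_oracle(self, rng):
        a = rng.random(30)
        b = rng.random(45) ** 2
        report = compare_rpp_distributions(a, b)
        assert report.statistic == pytest.approx(ks_oracle(a, b), abs=1e-12)

    def test_histograms_cover_samples(self, rng):
        a = rng.random(30)
        b = rng.random(20)
        report = compare_rpp_distributions(a, b)
        assert report.histogram_a.sum() == 30
        assert report.histogram_b.sum() == 20
        assert len(report.bin_edges) == 11
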