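"""Residue- and chain-based performance metrics and comparison statistics.

Residue-based evaluation pools all residues across chains; chain-based
evaluation computes each metric per chain and averages unweighted over
chains. Predictor comparisons test paired per-chain MCC values with a
Shapiro-Wilk normality gate choosing between the paired t-test and the
Wilcoxon signed-rank test. The non-binder specificity diagnostic is the
ratio of positive predictions (RPP), compared between populations with the
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hybrid import PredictionResult
from .io_formats import DataError


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def from_calls(calls: np.ndarray, labels: np.ndarray) -> "ConfusionCounts":
        calls = np.asarray(calls, bool)
        labels = np.asarray(labels, bool)
        if calls.shape != labels.shape:
            raise DataError("calls and labels differ in length")
        return ConfusionCounts(
            tp=int(np.sum(calls & labels)),
            fp=int(np.sum(calls & ~labels)),
            fn=int(np.sum(~calls & labels)),
            tn=int(np.sum(~calls & ~labels)),
        )


@dataclass
class MetricSet:
    recall: float
    precision: float
    f1: float
    acc: float
    mcc: float
    auc: float | None = None
    mcc_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "recall": self.recall, "precision": self.precision,
            "F1": self.f1, "ACC": self.acc, "MCC": self.mcc, "AUC": self.auc,
        }


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Standard confusion-matrix metrics.

    Degenerate denominators resolve to 0 (flagged for MCC) so chain
    averaging stays total.
    """
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    acc = (c.tp + c.tn) / c.total if c.total else 0.0
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return MetricSet(recall, precision, f1, acc, 0.0, mcc_defined=False)
    mcc = (c.tp * c.tn - c.fp * c.fn) / denom
    return MetricSet(recall, precision, f1, acc, mcc)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney rank statistic with midrank ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined: one class absent")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def residue_metrics(scores: np.ndarray, calls: np.ndarray,
                    labels: np.ndarray) -> MetricSet:
    """Pooled per-residue metrics, including AUC when both classes occur."""
    counts = ConfusionCounts.from_calls(calls, labels)
    ms = metrics_from_counts(counts)
    labels = np.asarray(labels, bool)
    if labels.any() and not labels.all():
        ms.auc = auc(scores, labels)
    return ms


@dataclass
class EvaluationReport:
    level: str
    metrics: MetricSet
    per_chain: dict[str, MetricSet] = field(default_factory=dict)
    n_chains_auc: int = 0
    n_chains_mcc_undefined: int = 0

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "metrics": self.metrics.as_dict(),
            "per_chain": {k: v.as_dict() for k, v in self.per_chain.items()},
            "n_chains_auc": self.n_chains_auc,
            "n_chains_mcc_undefined": self.n_chains_mcc_undefined,
        }


def residue_based_evaluation(results: list[PredictionResult],
                             labels: dict[str, np.ndarray]) -> EvaluationReport:
    scores = np.concatenate([r.cscores for r in results])
    calls = np.concatenate([r.calls for r in results])
    y = np.concatenate([np.asarray(labels[r.chain_id], bool) for r in results])
    return EvaluationReport(level="residue",
                            metrics=residue_metrics(scores, calls, y))


def chain_based_evaluation(results: list[PredictionResult],
                           labels: dict[str, np.ndarray]) -> EvaluationReport:
    """Per-chain metrics averaged unweighted over chains.

    Chains with an undefined MCC contribute 0 to the MCC average (counted in
    the report); chains lacking one class are excluded from the AUC average.
    """
    if not results:
        raise DataError("no chains to evaluate")
    per_chain: dict[str, MetricSet] = {}
    aucs = []
    n_undef = 0
    for r in results:
        y = np.asarray(labels[r.chain_id], bool)
        ms = metrics_from_counts(ConfusionCounts.from_calls(r.calls, y))
        if y.any() and not y.all():
            ms.auc = auc(r.cscores, y)
            aucs.append(ms.auc)
        if not ms.mcc_defined:
            n_undef += 1
        per_chain[r.chain_id] = ms
    mean = MetricSet(
        recall=float(np.mean([m.recall for m in per_chain.values()])),
        precision=float(np.mean([m.precision for m in per_chain.values()])),
        f1=float(np.mean([m.f1 for m in per_chain.values()])),
        acc=float(np.mean([m.acc for m in per_chain.values()])),
        mcc=float(np.mean([m.mcc for m in per_chain.values()])),
        auc=float(np.mean(aucs)) if aucs else None,
    )
    return EvaluationReport(level="chain", metrics=mean, per_chain=per_chain,
                            n_chains_auc=len(aucs),
                            n_chains_mcc_undefined=n_undef)


# ---------------------------------------------------------------------------
# Predictor comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    test_name: str
    statistic: float | None
    p_value: float | None
    significant: bool
    shapiro_p: float | None = None


def compare_predictors(mcc_a: np.ndarray, mcc_b: np.ndarray,
                       alpha: float = 0.05) -> ComparisonReport:
    """Paired comparison of per-chain MCC vectors.

    The Shapiro-Wilk test on the paired differences (at the same alpha)
    gates the choice: normal-looking differences use the paired t-test,
    otherwise the Wilcoxon signed-rank test.
    """
    a = np.asarray(mcc_a, float)
    b = np.asarray(mcc_b, float)
    if a.shape != b.shape:
        raise DataError("paired MCC vectors differ in length")
    if len(a) < 5:
        raise DataError("need at least 5 paired chains")
    diffs = a - b
    if np.all(diffs == 0):
        return ComparisonReport("no-difference", None, None, False)
    sw_stat, sw_p = stats.shapiro(diffs)
    if sw_p > alpha:
        stat, p = stats.ttest_rel(a, b)
        name = "paired-t"
    else:
        stat, p = stats.wilcoxon(a, b)
        name = "wilcoxon-signed-rank"
    return ComparisonReport(name, float(stat), float(p), bool(p < alpha),
                            shapiro_p=float(sw_p))


# ---------------------------------------------------------------------------
# Non-binder specificity (RPP)
# ---------------------------------------------------------------------------

def rpp(result: PredictionResult) -> float:
    """Ratio of positive predictions: predicted binding / chain length."""
    return float(np.mean(np.asarray(result.calls, bool)))


@dataclass
class KsReport:
    statistic: float
    p_value: float
    histogram_a: np.ndarray
    histogram_b: np.ndarray
    bin_edges: np.ndarray


def compare_rpp_distributions(rpp_a: np.ndarray, rpp_b: np.ndarray) -> KsReport:
    """Two-sample Kolmogorov-Smirnov comparison of RPP distributions.

    Also reports 0.1-width histograms of both samples for plotting.
    """
    a = np.asarray(rpp_a, float)
    b = np.asarray(rpp_b, float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("both RPP samples must be non-empty")
    stat, p = stats.ks_2samp(a, b, method="auto")
    edges = np.arange(0.0, 1.0 + 1e-9, 0.1)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    return KsReport(float(stat), float(p), ha, hb, edges)
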