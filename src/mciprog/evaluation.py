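"""Performance metrics, fold aggregation and model-comparison statistics.

AUC is computed by the rank (Mann-Whitney) formula — the fraction of
(positive, negative) pairs ordered correctly, ties counted one half — which
equals trapezoidal integration of the ROC curve.  MCC follows the standard
confusion-matrix formula with the zero-marginal -> 0 convention.  R^2 is the
coefficient of determination and may be negative for poor predictors.

Model comparison follows the fold-level design: each model contributes one
metric value per (outer fold, inner fold) pair, and pairs of models are
compared with a two-sided Mann-Whitney U-test over those values, exact for
small tie-free samples.  Confidence intervals are percentile bootstrap over
subjects of the pooled test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from .errors import ComparisonError, UndefinedMetricError


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank formula, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_standard_error(a: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate.

    Uses the exponential approximation Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    if n_pos < 1 or n_neg < 1:
        raise UndefinedMetricError("AUC SE needs both classes")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a ** 2 / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a ** 2)
           + (n_neg - 1) * (q2 - a ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def mcc(scores_or_labels: np.ndarray, labels: np.ndarray,
        threshold: float | None = 0.5) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero.

    Probabilistic scores are thresholded at ``threshold`` (pass ``None`` for
    already-binary predictions).
    """
    y_true = np.asarray(labels).astype(int)
    if y_true.size == 0:
        raise UndefinedMetricError("empty input")
    pred = np.asarray(scores_or_labels)
    y_pred = pred.astype(int) if threshold is None else \
        (pred.astype(float) >= threshold).astype(int)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(y_true, y_pred))


def r_squared(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    predicted = np.asarray(predicted, float)
    truth = np.asarray(truth, float)
    if truth.size < 2 or np.var(truth) == 0:
        raise UndefinedMetricError(
            "R^2 needs >= 2 subjects with variable truth")
    ss_res = float(np.sum((truth - predicted) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def mann_whitney_test(values_a: Sequence[float], values_b: Sequence[float],
                      alpha: float = 0.05
                      ) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U-test: (U_a, p, significant at alpha).

    Exact null distribution for small tie-free samples (both n <= 8),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise UndefinedMetricError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 8) else \
        "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p, p < alpha


def bootstrap_ci(metric: Callable[[np.ndarray, np.ndarray], float],
                 scores: np.ndarray, labels: np.ndarray,
                 reps: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval for a metric of (scores, labels).

    Subjects are resampled with replacement; resamples where the metric is
    undefined (e.g. a single class drawn) are redrawn.
    """
    if reps < 100:
        raise UndefinedMetricError("reps must be >= 100")
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    n = scores.shape[0]
    rng = np.random.default_rng([seed, 41])
    values = np.empty(reps)
    max_redraws = 100 * reps
    drawn = 0
    for r in range(reps):
        while True:
            drawn += 1
            if drawn > max_redraws:
                raise UndefinedMetricError(
                    "metric undefined for (almost) all bootstrap resamples")
            idx = rng.integers(0, n, n)
            try:
                values[r] = metric(scores[idx], labels[idx])
                break
            except UndefinedMetricError:
                continue
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(values, lo)),
            float(np.quantile(values, 1.0 - lo)))


@dataclass
class MetricReport:
    """Per-fold metric values and summaries for one model/task."""

    model: str
    task: str                      # "progression" | "slope"
    fold_values: pd.DataFrame      # columns outer_fold, inner_fold, metric,
                                   # value
    plan_signature: str = ""
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def values(self, metric: str) -> np.ndarray:
        sel = self.fold_values[self.fold_values["metric"] == metric]
        return sel["value"].to_numpy(float)

    def outer_means(self, metric: str) -> pd.Series:
        sel = self.fold_values[self.fold_values["metric"] == metric]
        return sel.groupby("outer_fold")["value"].mean()


def compare_models(reports: Sequence[MetricReport], metric: str,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Mann-Whitney p-values over fold-level metric values.

    All reports must share the same split plan; each contributes its full
    set of (outer x inner) fold values.
    """
    sigs = {r.plan_signature for r in reports}
    if len(sigs) > 1:
        raise ComparisonError("reports come from different split plans")
    names = [r.model for r in reports]
    out = pd.DataFrame(np.ones((len(reports), len(reports))),
                       index=names, columns=names)
    for i, ra in enumerate(reports):
        for j, rb in enumerate(reports):
            if j <= i:
                continue
            _, p, _ = mann_whitney_test(ra.values(metric), rb.values(metric),
                                        alpha)
            out.iloc[i, j] = p
            out.iloc[j, i] = p
    return out
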