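"""Clustering-quality metrics and replication summaries.

The misclassification error rate is the minimum fraction of disagreements
over all one-to-one matchings of predicted to true cluster labels, obtained
by optimal assignment on the confusion matrix.  Rand and adjusted Rand
(Hubert–Arabie) indices delegate to scikit-learn's pair-counting
implementations.  Replication summaries report, per metric, the mean, the
RMSE relative to the ideal value (0 for error rate, 1 for the Rand indices),
the sample standard deviation, and the fraction of replicates on which one
method beats (or, optionally, is not worse than) another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, rand_score

from .exceptions import InvalidParameterError

__all__ = [
    "ClusteringComparison",
    "ReplicationSummary",
    "error_rate",
    "rand_index",
    "adjusted_rand_index",
    "compare_partitions",
    "summarize_replicates",
]


def _check_lengths(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise InvalidParameterError(f"label vectors differ in length ({a.size} vs {b.size})")
    return a, b


def error_rate(true_labels, pred_labels) -> float:
    """Permutation-minimised misclassification fraction.

    Builds the confusion matrix and finds the one-to-one relabelling of
    predicted clusters that maximises agreement (Hungarian assignment).
    """
    t, p = _check_lengths(true_labels, pred_labels)
    t_codes, _ = _codes(t)
    p_codes, _ = _codes(p)
    k = max(t_codes.max(), p_codes.max()) + 1
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (t_codes, p_codes), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return 1.0 - confusion[rows, cols].sum() / t.size


def _codes(labels):
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, uniq


def rand_index(true_labels, pred_labels) -> float:
    """Plain Rand index: concordant pairs / all pairs."""
    t, p = _check_lengths(true_labels, pred_labels)
    return float(rand_score(t, p))


def adjusted_rand_index(true_labels, pred_labels) -> float:
    """Hubert–Arabie chance-adjusted Rand index."""
    t, p = _check_lengths(true_labels, pred_labels)
    return float(adjusted_rand_score(t, p))


@dataclass
class ClusteringComparison:
    """All three agreement metrics between two partitions of n items."""

    error_rate: float
    rand: float
    adjusted_rand: float
    n_items: int


def compare_partitions(true_labels, pred_labels) -> ClusteringComparison:
    t, p = _check_lengths(true_labels, pred_labels)
    return ClusteringComparison(
        error_rate=error_rate(t, p),
        rand=rand_index(t, p),
        adjusted_rand=adjusted_rand_index(t, p),
        n_items=t.size,
    )


@dataclass
class MetricSummary:
    mean: float
    rmse: float  # deviation from the ideal value of the metric
    sd: float  # sample standard deviation (divisor n-1)


@dataclass
class ReplicationSummary:
    """Footer block of a simulation table for one metric and two methods."""

    metric: str
    method_a: MetricSummary
    method_b: MetricSummary | None
    proportion_better: float | None
    n_replicates: int


_METRIC_REFERENCE = {"error_rate": 0.0, "rand": 1.0, "adjusted_rand": 1.0}
_LOWER_IS_BETTER = {"error_rate": True, "rand": False, "adjusted_rand": False}


def _summary(values: np.ndarray, reference: float) -> MetricSummary:
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return MetricSummary(
        mean=float(values.mean()),
        rmse=float(np.sqrt(np.mean((values - reference) ** 2))),
        sd=sd,
    )


def summarize_replicates(
    metric: str,
    values_a,
    values_b=None,
    strict: bool = True,
) -> ReplicationSummary:
    """Mean / RMSE / SD per method and the fraction of replicates where
    method A is better (lower error, higher index).

    ``strict=True`` counts strict wins; ``strict=False`` counts "not worse"
    (ties included), the convention used when comparing under the baseline's
    own generative model.
    """
    if metric not in _METRIC_REFERENCE:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    ref = _METRIC_REFERENCE[metric]
    a = np.asarray(values_a, dtype=float)
    summary_a = _summary(a, ref)
    summary_b = None
    proportion = None
    if values_b is not None:
        b = np.asarray(values_b, dtype=float)
        if b.size != a.size:
            raise InvalidParameterError("replicate vectors differ in length")
        summary_b = _summary(b, ref)
        if _LOWER_IS_BETTER[metric]:
            wins = a < b if strict else a <= b
        else:
            wins = a > b if strict else a >= b
        proportion = float(wins.mean())
    return ReplicationSummary(
        metric=metric,
        method_a=summary_a,
        method_b=summary_b,
        proportion_better=proportion,
        n_replicates=a.size,
    )
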