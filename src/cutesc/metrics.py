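"""Internal and external cluster-validity criteria.

External criteria compare a predicted partition to ground truth through the
contingency table (true classes × predicted clusters) and the induced
counts over point pairs: pair Jaccard, precision, recall, Fowlkes-Mallows,
Dice (equivalently pairwise F1), adjusted Rand index, and adjusted mutual
information with the exact hypergeometric expected-MI correction.  The
internal criterion is the Calinski-Harabasz variance-ratio score used by
the iterative driver.

Predicted outlier points (label -1) are by default promoted to singleton
clusters so that no point is dropped and over-noising is penalized
symmetrically; pass ``outliers="exclude"`` to drop them instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import UndefinedMetricError, UndefinedScoreError
from .geometry import PointSet

__all__ = [
    "ContingencyTable",
    "PairCounts",
    "contingency",
    "pair_counts",
    "jaccard",
    "precision",
    "recall",
    "fowlkes_mallows",
    "dice",
    "pairwise_f1",
    "adjusted_rand",
    "adjusted_mutual_information",
    "calinski_harabasz",
    "external_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts matrix: rows are true classes, columns predicted clusters."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("contingency counts must be a 2-D matrix")
        if np.any(counts < 0):
            raise ValueError("contingency counts must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class PairCounts:
    """Agreement counts over the n(n-1)/2 unordered point pairs."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _resolve_outliers(pred: np.ndarray, policy: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (keep_mask, relabeled_pred) applying the outlier policy."""
    pred = np.asarray(pred)
    mask = np.ones(pred.shape[0], dtype=bool)
    if not np.any(pred == -1):
        return mask, pred
    if policy == "singleton":
        out = pred.copy()
        hi = pred.max(initial=-1) + 1
        idx = np.flatnonzero(pred == -1)
        out[idx] = hi + np.arange(idx.size)
        return mask, out
    if policy == "exclude":
        return pred != -1, pred
    raise ValueError(f"unknown outlier policy {policy!r}")


def contingency(
    true_labels, pred_labels, *, outliers: str = "singleton"
) -> ContingencyTable:
    """Build the true-class × predicted-cluster contingency table."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape or true_labels.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length, got "
            f"{true_labels.shape} vs {pred_labels.shape}"
        )
    keep, pred_labels = _resolve_outliers(pred_labels, outliers)
    true_labels, pred_labels = true_labels[keep], pred_labels[keep]
    _, ti = np.unique(true_labels, return_inverse=True)
    _, pi = np.unique(pred_labels, return_inverse=True)
    r, c = ti.max() + 1, pi.max() + 1
    counts = np.zeros((r, c), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ContingencyTable(counts)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def pair_counts(t: ContingencyTable) -> PairCounts:
    """Derive TP/FP/FN/TN pair counts from the contingency table alone."""
    n = t.n
    tp = int(_comb2(t.counts).sum())
    fp = int(_comb2(t.col_marginals).sum()) - tp
    fn = int(_comb2(t.row_marginals).sum()) - tp
    total = n * (n - 1) // 2
    return PairCounts(tp=tp, fp=fp, fn=fn, tn=total - tp - fp - fn)


def _require_pairs(p: PairCounts):
    if p.total < 1:
        raise UndefinedMetricError("pair-counting criteria need at least 2 points")


def _ratio(num: float, den: float) -> float:
    # 0/0 convention: vacuous agreement counts as 0 unless handled upstream
    return num / den if den > 0 else 0.0


def jaccard(p: PairCounts) -> float:
    _require_pairs(p)
    if p.fp == 0 and p.fn == 0:
        return 1.0
    return _ratio(p.tp, p.tp + p.fp + p.fn)


def precision(p: PairCounts) -> float:
    _require_pairs(p)
    if p.fp == 0 and p.fn == 0:
        return 1.0
    return _ratio(p.tp, p.tp + p.fp)


def recall(p: PairCounts) -> float:
    _require_pairs(p)
    if p.fp == 0 and p.fn == 0:
        return 1.0
    return _ratio(p.tp, p.tp + p.fn)


def fowlkes_mallows(p: PairCounts) -> float:
    """Geometric mean of pair precision and recall."""
    _require_pairs(p)
    if p.fp == 0 and p.fn == 0:
        return 1.0
    return float(np.sqrt(_ratio(p.tp, p.tp + p.fp) * _ratio(p.tp, p.tp + p.fn)))


def dice(p: PairCounts) -> float:
    """Pairwise Dice coefficient, identical to the pairwise F1 score."""
    _require_pairs(p)
    if p.fp == 0 and p.fn == 0:
        return 1.0
    return _ratio(2 * p.tp, 2 * p.tp + p.fp + p.fn)


pairwise_f1 = dice


def adjusted_rand(t: ContingencyTable) -> float:
    """Adjusted Rand index: pair agreement corrected for chance."""
    n = t.n
    if n < 2:
        raise UndefinedMetricError("ARI needs at least 2 points")
    index = float(_comb2(t.counts).sum())
    sum_a = float(_comb2(t.row_marginals).sum())
    sum_b = float(_comb2(t.col_marginals).sum())
    expected = sum_a * sum_b / _comb2(np.int64(n))
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        # both partitions trivial (all-singletons or all-in-one): perfect
        return 1.0
    return (index - expected) / (maximum - expected)


def _entropy(marginals: np.ndarray, n: int) -> float:
    p = marginals[marginals > 0] / n
    return float(-np.sum(p * np.log(p)))


def _mutual_information(t: ContingencyTable) -> float:
    n = t.n
    nz = t.counts > 0
    nij = t.counts[nz].astype(float)
    outer = np.outer(t.row_marginals, t.col_marginals)[nz].astype(float)
    return float(np.sum((nij / n) * (np.log(nij * n) - np.log(outer))))


def _expected_mutual_information(t: ContingencyTable) -> float:
    """Exact E[MI] under the hypergeometric model of random tables with
    fixed marginals."""
    n = t.n
    a = t.row_marginals.astype(np.int64)
    b = t.col_marginals.astype(np.int64)
    lg = gammaln
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term1 = (nij / n) * (np.log(n * nij) - np.log(ai * bj))
            term2 = np.exp(
                lg(ai + 1)
                + lg(bj + 1)
                + lg(n - ai + 1)
                + lg(n - bj + 1)
                - lg(n + 1)
                - lg(nij + 1)
                - lg(ai - nij + 1)
                - lg(bj - nij + 1)
                - lg(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(term1 * term2))
    return emi


def adjusted_mutual_information(
    t: ContingencyTable, *, average_method: str = "max"
) -> float:
    """AMI = (MI - E[MI]) / (norm(H(U), H(V)) - E[MI]).

    ``average_method`` selects the normalization of the two entropies:
    ``max`` (default), ``min``, ``arithmetic`` or ``geometric``.
    """
    if t.n < 2:
        raise UndefinedMetricError("AMI needs at least 2 points")
    hu = _entropy(t.row_marginals, t.n)
    hv = _entropy(t.col_marginals, t.n)
    if hu == 0.0 and hv == 0.0:
        # both sides a single cluster: identical trivial partitions
        return 1.0
    mi = _mutual_information(t)
    emi = _expected_mutual_information(t)
    norms = {
        "max": max(hu, hv),
        "min": min(hu, hv),
        "arithmetic": 0.5 * (hu + hv),
        "geometric": float(np.sqrt(hu * hv)),
    }
    try:
        norm = norms[average_method]
    except KeyError:
        raise ValueError(f"unknown average_method {average_method!r}") from None
    denom = norm - emi
    if denom == 0.0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def calinski_harabasz(points: PointSet | np.ndarray, labels) -> float:
    """Calinski-Harabasz variance-ratio criterion.

    CH = [SSB / (k-1)] / [SSW / (n-k)] where SSB/SSW are the between- and
    within-cluster sums of squared distances to the respective centroids.
    Outlier-labeled points (-1) are excluded.  Raises
    :class:`UndefinedScoreError` for k < 2 or zero within-cluster scatter.
    """
    coords = points.coords if isinstance(points, PointSet) else np.asarray(points, float)
    labels = np.asarray(labels)
    if isinstance(labels, np.ndarray) and labels.shape[0] != coords.shape[0]:
        raise ValueError("labels length must match point count")
    keep = labels != -1
    coords, labels = coords[keep], labels[keep]
    uniq = np.unique(labels)
    k, n = uniq.size, coords.shape[0]
    if k < 2:
        raise UndefinedScoreError(f"score needs k >= 2 clusters, got {k}")
    if n <= k:
        raise UndefinedScoreError("score needs more points than clusters")
    mu = coords.mean(axis=0)
    ssb = 0.0
    ssw = 0.0
    for c in uniq:
        pts = coords[labels == c]
        mu_c = pts.mean(axis=0)
        ssb += pts.shape[0] * float(np.sum((mu_c - mu) ** 2))
        ssw += float(np.sum((pts - mu_c) ** 2))
    if ssw == 0.0:
        raise UndefinedScoreError("zero within-cluster scatter")
    return (ssb / (k - 1)) / (ssw / (n - k))


def external_report(true_labels, pred_labels, *, outliers: str = "singleton") -> dict:
    """All external criteria for one (truth, prediction) pair as a flat dict."""
    t = contingency(true_labels, pred_labels, outliers=outliers)
    p = pair_counts(t)
    return {
        "jaccard": float(jaccard(p)),
        "precision": float(precision(p)),
        "recall": float(recall(p)),
        "fowlkes_mallows": float(fowlkes_mallows(p)),
        "dice": float(dice(p)),
        "ari": float(adjusted_rand(t)),
        "ami": float(adjusted_mutual_information(t)),
    }
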