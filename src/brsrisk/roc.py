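"""ROC curves, AUC with confidence intervals, and Youden-index cutoffs.

Thresholds are the midpoints between consecutive distinct score values plus
-inf/+inf sentinels, so optimal cutoffs land on half-units for integer-valued
ECG measurements (e.g. a QTc cutoff of 433.5 ms). A case is called positive
when its score is >= the threshold. The trapezoidal area under the stored
curve equals the Mann-Whitney statistic (ties counted 1/2) exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from ._base import DomainError

__all__ = ["RocResult", "roc_curve", "youden_cutoff", "auc_ci", "mann_whitney_auc"]


@dataclass(frozen=True)
class RocResult:
    """A full ROC curve with its AUC and Youden summary.

    ``thresholds`` ascend from -inf to +inf; ``sensitivity`` and
    ``specificity`` are aligned with them (sensitivity nonincreasing in the
    threshold). ``youden_cutoff`` is the smallest threshold attaining the
    maximal Youden J = sensitivity + specificity - 1.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    auc_ci: Optional[tuple[float, float]] = None


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    if scores.ndim != 1 or scores.shape != labels.shape:
        raise DomainError("scores and labels must be aligned 1-d arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise DomainError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise DomainError("both classes must be present")
    return scores, labels


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the probability a random case outscores a random control
    (ties counted 1/2), via mid-ranks."""
    scores, labels = _check_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # mid-ranks
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> RocResult:
    """ROC curve over midpoint thresholds with trapezoidal AUC and Youden J."""
    scores, labels = _check_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])

    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    sens = np.array([(pos_scores >= t).mean() for t in thresholds])
    spec = np.array([(neg_scores < t).mean() for t in thresholds])

    # integrate over (fpr, tpr) with fpr increasing (descending threshold)
    fpr = (1.0 - spec)[::-1]
    tpr = sens[::-1]
    auc = float(np.trapezoid(tpr, fpr))

    j = sens + spec - 1.0
    j_max = float(j.max())
    cutoff = float(thresholds[np.argmax(j >= j_max - 1e-12)])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=cutoff,
        youden_j=j_max,
    )


def youden_cutoff(roc: RocResult) -> tuple[float, float]:
    """(cutoff, J) maximizing sensitivity + specificity - 1.

    Ties broken toward the smallest qualifying cutoff.
    """
    if roc.thresholds.size == 0:
        raise DomainError("empty ROC")
    return roc.youden_cutoff, roc.youden_j


def _delong_variance(scores, labels) -> tuple[float, float]:
    """DeLong AUC and its variance via placement values."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    m, n = len(pos), len(neg)
    # placement of each case among controls and vice versa (ties 1/2)
    v10 = np.array([((s > neg).sum() + 0.5 * (s == neg).sum()) / n for s in pos])
    v01 = np.array([((pos > s).sum() + 0.5 * (pos == s).sum()) / m for s in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% (by default) CI for the AUC, clipped to [0, 1].

    ``method="delong"`` uses the DeLong placement-value variance with a
    normal interval (deterministic); ``method="bootstrap"`` uses a
    class-stratified percentile bootstrap with a fixed seed. DeLong needs at
    least 2 subjects per class, else it falls back to the bootstrap with a
    warning.
    """
    scores, labels = _check_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if method == "delong" and min(n_pos, n_neg) < 2:
        warnings.warn(
            "DeLong CI needs >= 2 subjects per class; falling back to bootstrap",
            stacklevel=2,
        )
        method = "bootstrap"
    if method == "delong":
        auc, var = _delong_variance(scores, labels)
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [
                    rng.choice(pos_idx, size=n_pos, replace=True),
                    rng.choice(neg_idx, size=n_neg, replace=True),
                ]
            )
            aucs[b] = mann_whitney_auc(scores[take], labels[take])
        lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return (max(0.0, float(lo)), min(1.0, float(hi)))
    raise DomainError(f"unknown AUC CI method {method!r}")
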