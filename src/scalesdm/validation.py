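"""Predictive-power diagnostics: ROC/AUC, CV-chosen threshold, confusion matrix.

AUC is computed as the normalised Mann-Whitney statistic,
``P(score+ > score-) + 0.5 P(tie)`` — identically the area under the
empirical ROC curve.  The classification threshold maximises
sensitivity + specificity on held-out folds of a stratified k-fold split
(k = 5 by default) and the fold thresholds are averaged; ties at the
optimum resolve to the higher threshold (more conservative presence calls).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = ["auc", "optimal_threshold", "confusion_stats", "roc_points",
           "RocResult", "evaluate_classifier"]


def _check(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation."""
    s, y = _check(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    r = rankdata(s)
    u = float(r[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, sensitivity, specificity) over every distinct score cut.

    Thresholds are the distinct scores (prediction rule: score >= threshold
    => presence), bracketed by +inf for the all-negative rule.
    """
    s, y = _check(scores, labels)
    thr = np.concatenate([[np.inf], np.unique(s)[::-1]])
    n1 = y.sum()
    n0 = y.size - n1
    sens = np.empty(thr.size)
    spec = np.empty(thr.size)
    for i, t in enumerate(thr):
        pred = s >= t
        sens[i] = np.sum(pred & (y == 1)) / n1
        spec[i] = np.sum(~pred & (y == 0)) / n0
    return thr, sens, spec


def _best_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity.

    Ties at the optimum resolve to the higher cut score; the returned value
    is the midpoint between that cut and the next score below it, so it sits
    inside the separating gap (and averages across CV folds stay there).
    """
    thr, sens, spec = roc_points(scores, labels)
    crit = sens + spec
    cand = thr[np.isclose(crit, crit.max())]
    cand = cand[np.isfinite(cand)]
    if cand.size == 0:     # all-negative rule won: use just above max score
        return float(np.max(scores)) + 1.0
    cut = float(cand.max())
    below = scores[scores < cut]
    return 0.5 * (cut + float(below.max())) if below.size else cut - 1.0


def optimal_threshold(scores, labels, k_folds: int = 5, seed: int = 0) -> float:
    """Cross-validated classification threshold.

    Per stratified fold, the threshold maximising held-out
    sensitivity + specificity; the returned value is the mean over folds.
    """
    s, y = _check(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if min(n0, n1) < k_folds:
        raise ValueError(
            f"cannot stratify {k_folds} folds with class counts ({n0}, {n1})"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    thr = [
        _best_threshold(s[test], y[test])
        for _, test in skf.split(s.reshape(-1, 1), y)
    ]
    return float(np.mean(thr))


@dataclasses.dataclass
class RocResult:
    """Classifier evaluation: AUC, threshold, confusion matrix and rates (%)."""

    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    def summary(self) -> str:
        return (
            f"AUC {self.auc:.3f} | threshold {self.threshold:.4f} | "
            f"accuracy {self.accuracy:.1f}% | sensitivity {self.sensitivity:.1f}% | "
            f"specificity {self.specificity:.1f}%"
        )


def confusion_stats(scores, labels, threshold: float) -> RocResult:
    """Confusion matrix and rates at a fixed threshold (score >= t => presence)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s, y = _check(scores, labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return RocResult(auc=auc(s, y), threshold=float(threshold),
                     tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_classifier(scores, labels, k_folds: int = 5, seed: int = 0) -> RocResult:
    """AUC plus in-sample confusion matrix at the CV-chosen threshold."""
    t = optimal_threshold(scores, labels, k_folds=k_folds, seed=seed)
    return confusion_stats(scores, labels, t)
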