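"""Score thresholding, ROC curves and the trapezoidal AUROC estimate.

A :class:`ScoreSet` pairs per-case scores (probabilities or raw values) with
binary ground truth.  Dichotomising at a threshold uses the strict rule
"score > threshold is a positive call" -- i.e. a score exactly equal to the
threshold is a negative call -- and the same rule is used by the simulation
engine so a 50% probability threshold behaves consistently everywhere.

The empirical ROC curve steps once per distinct score value (ties grouped),
and the trapezoidal area under it equals the Mann-Whitney rank statistic
U/(n+ * n-) with ties counted half, which tests use as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confusion import ConfusionMatrix

__all__ = ["ScoreSet", "RocCurve", "threshold_classify", "roc_curve", "auroc_trapezoid", "auroc"]


@dataclass(frozen=True)
class ScoreSet:
    """Parallel arrays of continuous scores and binary truth labels."""

    scores: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        t = np.asarray(self.truth)
        if s.ndim != 1 or t.ndim != 1 or len(s) != len(t):
            raise ValueError("scores and truth must be 1-D arrays of equal length")
        if len(s) == 0:
            raise ValueError("score set is empty")
        if not np.all(np.isin(t, (0, 1))):
            raise ValueError("truth labels must be 0 or 1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "truth", t.astype(np.int8))

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def n_positive(self) -> int:
        return int(self.truth.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self) - self.truth.sum())


@dataclass(frozen=True)
class RocCurve:
    """ROC points (fpr, tpr), anchored at (0,0) and (1,1), non-decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fpr, dtype=float)
        t = np.asarray(self.tpr, dtype=float)
        if f.shape != t.shape or f.ndim != 1 or len(f) < 2:
            raise ValueError("curve needs matching 1-D fpr/tpr arrays with >= 2 points")
        if np.any((f < 0) | (f > 1) | (t < 0) | (t > 1)):
            raise ValueError("ROC coordinates must lie in [0, 1]")
        if np.any(np.diff(f) < 0) or np.any(np.diff(t) < 0):
            raise ValueError("ROC curve must be non-decreasing in both coordinates")
        object.__setattr__(self, "fpr", f)
        object.__setattr__(self, "tpr", t)

    @property
    def points(self) -> list:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def threshold_classify(s: ScoreSet, threshold: float) -> ConfusionMatrix:
    """Dichotomise scores at ``threshold`` (strict: score > threshold ⇒ positive call)."""
    pred = s.scores > threshold
    pos = s.truth == 1
    tp = int(np.count_nonzero(pred & pos))
    fp = int(np.count_nonzero(pred & ~pos))
    fn = int(np.count_nonzero(~pred & pos))
    tn = int(np.count_nonzero(~pred & ~pos))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def roc_curve(s: ScoreSet) -> RocCurve:
    """Empirical ROC curve with one step per distinct score value.

    Tied scores are grouped into a single threshold step, which makes the
    trapezoidal area award half credit for ties exactly as the rank
    statistic does.
    """
    n_pos, n_neg = s.n_positive, s.n_negative
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC curve requires at least one positive and one negative case")
    order = np.argsort(-s.scores, kind="stable")
    scores = s.scores[order]
    truth = s.truth[order]
    # group boundaries at distinct descending scores
    distinct = np.nonzero(np.diff(scores))[0]
    ends = np.append(distinct, len(scores) - 1)
    tps = np.cumsum(truth)[ends]
    fps = ends + 1 - tps
    fpr = np.concatenate(([0.0], fps / n_neg))
    tpr = np.concatenate(([0.0], tps / n_pos))
    return RocCurve(fpr=fpr, tpr=tpr)


def auroc_trapezoid(c: RocCurve) -> float:
    """Trapezoidal area under the ROC curve, in [0, 1]."""
    return float(np.trapezoid(c.tpr, c.fpr))


def auroc(s: ScoreSet) -> float:
    """Trapezoidal AUROC of a score set (curve construction + trapezoid rule)."""
    return auroc_trapezoid(roc_curve(s))
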