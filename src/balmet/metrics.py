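"""The balanced metric family (G4, P4, MCC_scaled) and the classical metric zoo.

G4 is the (optionally weighted) geometric mean of the four conditional
probabilities TPR, TNR, PPV, NPV; P4 is their harmonic mean; and the Matthews
correlation coefficient obeys the identity

    MCC = G4^2 - sqrt((1-TPR)(1-TNR)(1-PPV)(1-NPV)),

which rescaled as MCC_scaled = (MCC+1)/2 puts all three metrics on [0, 1].
When a dataset's prevalence equals the classifier's bias the three metrics
collapse onto the geometric/harmonic/arithmetic means of sensitivity and
specificity, and at prevalence = bias = 1/2 they all equal balanced accuracy.

The remaining single-matrix metrics found in the literature (accuracy, F1,
Youden's J, Cohen's kappa, ...) live in a registry addressed by lower-snake
names; see :data:`METRIC_REGISTRY`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from .confusion import ConfusionMatrix, RateQuartet, prevalence_bias, rates

__all__ = [
    "UndefinedMetricError",
    "MetricWeights",
    "g4",
    "p4",
    "mcc",
    "mcc_scaled",
    "balanced_family",
    "zoo_metric",
    "zoo_report",
    "METRIC_REGISTRY",
]


class UndefinedMetricError(ValueError):
    """A metric was requested on a matrix where a required denominator is zero.

    Distinct from a metric legitimately equal to 0: a defined rate of exactly
    0 yields G4 = P4 = 0 (the continuous limit), whereas an undefined rate
    raises this error.
    """


@dataclass(frozen=True)
class MetricWeights:
    """Exponent weights (w1..w4 for TPR, TNR, PPV, NPV) of the weighted G4.

    Non-negative, not all zero.  Scaling all weights by a positive constant
    leaves the weighted geometric mean unchanged.
    """

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 1.0

    def __post_init__(self) -> None:
        ws = self.as_tuple()
        if any(w < 0 or not math.isfinite(w) for w in ws):
            raise ValueError(f"weights must be finite and >= 0, got {ws}")
        if sum(ws) == 0:
            raise ValueError("at least one weight must be positive")

    def as_tuple(self) -> tuple:
        return (self.w1, self.w2, self.w3, self.w4)


EQUAL_WEIGHTS = MetricWeights()

CmOrQuartet = Union[ConfusionMatrix, RateQuartet]


def _as_quartet(x: CmOrQuartet) -> RateQuartet:
    return rates(x) if isinstance(x, ConfusionMatrix) else x

def _require_defined(q: RateQuartet, metric: str) -> tuple:
    missing = q.undefined_components()
    if missing:
        raise UndefinedMetricError(
            f"{metric} is undefined: zero denominator for {', '.join(missing)}"
        )
    return q.as_tuple()


def g4(x: CmOrQuartet, weights: MetricWeights = EQUAL_WEIGHTS) -> float:
    """Weighted geometric mean of TPR, TNR, PPV, NPV.

    ``(prod_i c_i**w_i) ** (1/sum_i w_i)``; equal weights give the plain
    fourth-root product.  Any component equal to 0 with positive weight makes
    the result 0; an undefined component raises
    :class:`UndefinedMetricError`.
    """
    comps = _require_defined(_as_quartet(x), "G4")
    ws = weights.as_tuple()
    total = sum(ws)
    if any(c == 0 and w > 0 for c, w in zip(comps, ws)):
        return 0.0
    # log-space for numerical symmetry under weight rescaling
    return math.exp(sum(w * math.log(c) for c, w in zip(comps, ws) if w > 0) / total)


def p4(x: CmOrQuartet) -> float:
    """Harmonic mean of the four conditional probabilities.

    ``4 / (1/TPR + 1/TNR + 1/PPV + 1/NPV)``; a component equal to 0 gives 0
    (the harmonic-mean limit), an undefined component raises.
    """
    comps = _require_defined(_as_quartet(x), "P4")
    if any(c == 0 for c in comps):
        return 0.0
    return 4.0 / sum(1.0 / c for c in comps)


def mcc(x: CmOrQuartet) -> float:
    """Matthews correlation coefficient via the G4 identity, in [-1, 1].

    ``MCC = G4^2 - sqrt((1-TPR)(1-TNR)(1-PPV)(1-NPV))``.  Equals the Pearson
    correlation of the two binary variables, i.e. the count form
    ``(TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.  A zero marginal
    makes the quartet partially undefined and raises
    :class:`UndefinedMetricError` (not the common "MCC = 0" convention).
    """
    t, n, p, v = _require_defined(_as_quartet(x), "MCC")
    return math.sqrt(t * n * p * v) - math.sqrt((1 - t) * (1 - n) * (1 - p) * (1 - v))


def mcc_scaled(x: CmOrQuartet) -> float:
    """MCC rescaled onto [0, 1]: ``(MCC + 1) / 2``."""
    return (mcc(x) + 1.0) / 2.0


def balanced_family(x: CmOrQuartet) -> tuple:
    """The (G4, P4, MCC_scaled) triple -- the balanced metric family.

    Convenience bundle used by the simulation engine and the MRMC bootstrap.
    """
    q = _as_quartet(x)
    return (g4(q), p4(q), mcc_scaled(q))


# ---------------------------------------------------------------------------
# metric zoo


def _accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.n


def _misclassification_rate(cm: ConfusionMatrix) -> float:
    return (cm.fp + cm.fn) / cm.n


def _two_rate(cm: ConfusionMatrix, a: str, b: str, metric: str, kind: str) -> float:
    q = rates(cm)
    x, y = getattr(q, a), getattr(q, b)
    if x is None or y is None:
        raise UndefinedMetricError(f"{metric} is undefined: zero denominator")
    if kind == "arith":
        return (x + y) / 2.0
    if kind == "geom":
        return math.sqrt(x * y)
    if kind == "harm":
        return 0.0 if x == 0 or y == 0 else 2.0 / (1.0 / x + 1.0 / y)
    if kind == "sum_minus_1":
        return x + y - 1.0
    raise AssertionError(kind)


def _balanced_accuracy(cm): return _two_rate(cm, "tpr", "tnr", "balanced_accuracy", "arith")
def _geometric_mean(cm): return _two_rate(cm, "tpr", "tnr", "geometric_mean", "geom")
def _fowlkes_mallows(cm): return _two_rate(cm, "tpr", "ppv", "fowlkes_mallows", "geom")
def _f1(cm): return _two_rate(cm, "tpr", "ppv", "f1", "harm")
def _youden_j(cm): return _two_rate(cm, "tpr", "tnr", "youden_j", "sum_minus_1")
def _markedness(cm): return _two_rate(cm, "ppv", "npv", "markedness", "sum_minus_1")


def _jaccard(cm: ConfusionMatrix) -> float:
    den = cm.tp + cm.fp + cm.fn
    if den == 0:
        raise UndefinedMetricError("jaccard is undefined: TP+FP+FN = 0")
    return cm.tp / den


def _ppa(cm: ConfusionMatrix) -> float:
    den = 2 * cm.tp + cm.fp + cm.fn
    if den == 0:
        raise UndefinedMetricError("percent_positive_agreement undefined: 2TP+FP+FN = 0")
    return 2 * cm.tp / den


def _pna(cm: ConfusionMatrix) -> float:
    den = 2 * cm.tn + cm.fp + cm.fn
    if den == 0:
        raise UndefinedMetricError("percent_negative_agreement undefined: 2TN+FP+FN = 0")
    return 2 * cm.tn / den


def _cohens_kappa(cm: ConfusionMatrix) -> float:
    den = (cm.tp + cm.fp) * (cm.fp + cm.tn) + (cm.tp + cm.fn) * (cm.fn + cm.tn)
    if den == 0:
        raise UndefinedMetricError("cohens_kappa is undefined: degenerate marginals")
    return 2.0 * (cm.tp * cm.tn - cm.fp * cm.fn) / den


#: Lower-snake registry of single-matrix metrics, one entry per classical metric.
METRIC_REGISTRY = {
    "accuracy": _accuracy,
    "misclassification_rate": _misclassification_rate,
    "balanced_accuracy": _balanced_accuracy,
    "geometric_mean": _geometric_mean,
    "fowlkes_mallows": _fowlkes_mallows,
    "f1": _f1,
    "jaccard": _jaccard,
    "percent_positive_agreement": _ppa,
    "percent_negative_agreement": _pna,
    "p4": p4,
    "youden_j": _youden_j,
    "markedness": _markedness,
    "cohens_kappa": _cohens_kappa,
    "mcc": mcc,
    # family conveniences addressable by name (used by the bootstrap/CLI)
    "g4": g4,
    "mcc_scaled": mcc_scaled,
}


def zoo_metric(name: str, cm: ConfusionMatrix) -> float:
    """Evaluate a registry metric by name on a confusion matrix."""
    try:
        fn = METRIC_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(METRIC_REGISTRY))
        raise KeyError(f"unknown metric {name!r}; known metrics: {known}") from None
    return fn(cm)


def zoo_report(cm: ConfusionMatrix) -> dict:
    """All registry metrics plus prevalence/bias; undefined entries are None."""
    out = {}
    prev, bias = prevalence_bias(cm)
    out["prevalence"] = prev
    out["bias"] = bias
    for name in METRIC_REGISTRY:
        try:
            out[name] = METRIC_REGISTRY[name](cm)
        except UndefinedMetricError:
            out[name] = None
    return out
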