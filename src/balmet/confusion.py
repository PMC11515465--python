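"""Confusion-matrix algebra: cell counts, conditional-probability rates, prevalence and bias.

A binary classifier compared against a reference standard yields a 2x2
contingency table of true/false positives/negatives.  Everything in this
package is computed from that table, so the two small containers here --
:class:`ConfusionMatrix` and :class:`RateQuartet` -- are the universal
currency.  Cells are stored as floats because reader-averaged matrices from
multi-reader studies are first-class inputs and need not be integers.

Zero denominators are handled explicitly: a rate whose denominator is zero is
``None`` (an "undefined" marker), never silently 0/0.  Downstream metrics
raise :class:`~balmet.metrics.UndefinedMetricError` on undefined components
rather than coercing them to zero, which would corrupt bootstrap
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ConfusionMatrix",
    "RateQuartet",
    "rates",
    "prevalence_bias",
    "parse_confusion_matrix",
    "format_confusion_matrix",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """A 2x2 truth-vs-prediction table.

    Parameters
    ----------
    tp, fp, fn, tn : float
        Cell counts: true positives, false positives, false negatives and
        true negatives.  Non-negative; non-integer values are allowed so that
        reader-averaged matrices can be represented exactly.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 or not math.isfinite(c) for c in cells):
            raise ValueError(f"confusion-matrix cells must be finite and >= 0, got {cells}")
        if sum(cells) <= 0:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def n(self) -> float:
        """Total number of observations, N = TP + FP + FN + TN."""
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> float:
        """Number of truly positive cases, TP + FN."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> float:
        """Number of truly negative cases, TN + FP."""
        return self.tn + self.fp

    def swap_labels(self) -> "ConfusionMatrix":
        """Return the matrix with the class labels exchanged (tp<->tn, fp<->fn)."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)

    def as_tuple(self) -> tuple:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class RateQuartet:
    """The four conditional probabilities of a confusion matrix.

    ``tpr`` (sensitivity/recall), ``tnr`` (specificity), ``ppv`` (precision)
    and ``npv``.  A component is ``None`` exactly when its denominator in the
    defining ratio is zero; defined components lie in [0, 1].
    """

    tpr: Optional[float]
    tnr: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    @property
    def all_defined(self) -> bool:
        return None not in (self.tpr, self.tnr, self.ppv, self.npv)

    def undefined_components(self) -> list:
        names = ("tpr", "tnr", "ppv", "npv")
        return [n for n in names if getattr(self, n) is None]

    def as_tuple(self) -> tuple:
        return (self.tpr, self.tnr, self.ppv, self.npv)

    def swap_labels(self) -> "RateQuartet":
        """Quartet under exchanged class labels: TPR<->TNR, PPV<->NPV."""
        return RateQuartet(tpr=self.tnr, tnr=self.tpr, ppv=self.npv, npv=self.ppv)


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def rates(cm: ConfusionMatrix) -> RateQuartet:
    """Compute TPR, TNR, PPV and NPV from a confusion matrix.

    TPR = TP/(TP+FN), TNR = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN).
    A component with a zero denominator is returned as ``None``.
    """
    return RateQuartet(
        tpr=_ratio(cm.tp, cm.tp + cm.fn),
        tnr=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def prevalence_bias(cm: ConfusionMatrix) -> tuple:
    """Prevalence (fraction truly positive) and bias (fraction predicted positive).

    Prevalence = (TP+FN)/N; bias = (TP+FP)/N.  Both are always defined
    because N > 0 is a class invariant.
    """
    n = cm.n
    return (cm.tp + cm.fn) / n, (cm.tp + cm.fp) / n


def parse_confusion_matrix(text: str, sep: str = ",") -> ConfusionMatrix:
    """Parse ``tp,fp,fn,tn`` from one line, or a 2x2 delimited block.

    The 2x2 block is read row-major as ``tp fp / fn tn`` (prediction rows,
    truth columns), matching :func:`format_confusion_matrix`.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) == 1:
        fields = [f for f in lines[0].replace(sep, " ").split() if f]
        if len(fields) != 4:
            raise ValueError(f"expected 4 cells on one line, got {len(fields)}: {lines[0]!r}")
        tp, fp, fn, tn = (float(f) for f in fields)
    elif len(lines) == 2:
        rows = [[float(f) for f in ln.replace(sep, " ").split() if f] for ln in lines]
        if any(len(r) != 2 for r in rows):
            raise ValueError("2x2 block must have two values per line")
        (tp, fp), (fn, tn) = rows
    else:
        raise ValueError(f"expected 1 or 2 non-empty lines, got {len(lines)}")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def format_confusion_matrix(cm: ConfusionMatrix, sep: str = ",") -> str:
    """Single-line ``tp,fp,fn,tn`` serialisation (round-trips via the parser)."""
    return sep.join(repr(c) for c in cm.as_tuple())
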