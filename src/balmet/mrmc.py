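"""Multi-reader multi-case (MRMC) data model and clustered bootstrap inference.

In an MRMC reader study several readers rate the same cases under one or
more modalities (e.g. radiologists with and without AI assistance).  Ratings
are ordinal (such as a 1-6 malignancy scale with "rating >= 4" meaning a
positive call); dichotomising each reader's ratings and averaging the
resulting per-reader confusion matrices cell-wise gives the reader-average
confusion matrix on which the balanced metric family is evaluated.

Uncertainty comes from a stratified, clustered, non-parametric bootstrap
with case resampling: each case is a cluster carrying all its readers'
ratings, and cases are resampled with replacement *within* the positive and
negative truth strata so every bootstrap replicate reproduces the original
disease prevalence exactly.  Between-modality differences support two
resampling modes -- ``nested`` draws case clusters independently per
modality (conservative: ignores the between-modality correlation present in
a fully-crossed design) and ``crossed`` applies one shared case resample to
both modalities.

The model-fitting surface is :class:`MrmcModel` / :class:`MrmcResults`;
the underlying operations (:func:`reader_average_cm`,
:func:`bootstrap_metric_ci`, :func:`bootstrap_difference_ci`) are plain
functions usable on their own.

Implementation note: because the reader-average matrix is linear in the
per-case, reader-averaged positive-call indicator, each case reduces to a
single number (the fraction of readers calling it positive).  Resampling
those per-case fractions within strata is exactly the clustered case
bootstrap, and lets replicates be drawn as vectorised index arrays.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .binormal import auroc_to_cohens_d
from .confusion import ConfusionMatrix, RateQuartet
from .metrics import METRIC_REGISTRY, UndefinedMetricError

__all__ = [
    "MrmcTable",
    "BootstrapResult",
    "MrmcModel",
    "MrmcResults",
    "reader_average_cm",
    "reconstruct_counts",
    "bootstrap_metric_ci",
    "bootstrap_difference_ci",
    "generate_synthetic_mrmc",
]

REQUIRED_COLUMNS = ("modality", "reader", "case", "truth", "rating")


@dataclass(frozen=True)
class MrmcTable:
    """Long-format MRMC ratings: one row per (modality, reader, case).

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``modality, reader, case, truth, rating``.  Truth is binary
        and must be constant per case across readers and modalities.
    positivity_cut : float
        A rating is a positive call iff ``rating >= positivity_cut``
        (e.g. >= 4 on a 1-6 malignancy scale).
    """

    data: pd.DataFrame
    positivity_cut: float = 4.0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"MRMC table is missing columns: {missing}")
        df = self.data
        if len(df) == 0:
            raise ValueError("MRMC table is empty")
        if not df["truth"].isin((0, 1)).all():
            raise ValueError("truth must be binary (0/1)")
        per_case = df.groupby("case")["truth"].nunique()
        bad = per_case[per_case > 1]
        if len(bad):
            raise ValueError(f"truth differs across readers/modalities for cases {list(bad.index)[:5]}")

    @property
    def modalities(self) -> list:
        return sorted(self.data["modality"].unique().tolist())

    @property
    def readers(self) -> list:
        return sorted(self.data["reader"].unique().tolist())

    def case_truth(self) -> pd.Series:
        """Truth label per case (cases are the clusters)."""
        return self.data.groupby("case")["truth"].first()

    @property
    def prevalence(self) -> float:
        t = self.case_truth()
        return float(t.mean())

    @classmethod
    def from_csv(cls, path, positivity_cut: float = 4.0) -> "MrmcTable":
        return cls(data=pd.read_csv(path), positivity_cut=positivity_cut)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def _positive_calls(t: MrmcTable, modality) -> pd.DataFrame:
    """Per (case, reader) binary positive-call table for one modality; validates completeness."""
    sub = t.data[t.data["modality"] == modality]
    if len(sub) == 0:
        raise KeyError(f"modality {modality!r} not present (have {t.modalities})")
    wide = sub.pivot_table(index="case", columns="reader", values="rating", aggfunc="first")
    if wide.isna().any().any():
        n_missing = int(wide.isna().sum().sum())
        raise ValueError(
            f"modality {modality!r} has {n_missing} missing (case, reader) ratings; "
            "each reader must rate every case of the modality"
        )
    return wide >= t.positivity_cut


def reader_average_cm(t: MrmcTable, modality) -> ConfusionMatrix:
    """Cell-wise mean of the per-reader confusion matrices for one modality.

    All readers are weighted equally; cells are generally non-integer and sum
    to the per-reader case total.
    """
    calls = _positive_calls(t, modality)
    truth = t.case_truth().loc[calls.index]
    frac = calls.mean(axis=1)  # fraction of readers calling each case positive
    pos, neg = frac[truth == 1], frac[truth == 0]
    return ConfusionMatrix(
        tp=float(pos.sum()),
        fn=float(len(pos) - pos.sum()),
        fp=float(neg.sum()),
        tn=float(len(neg) - neg.sum()),
    )


def reconstruct_counts(n_total: int, prevalence: float, q: RateQuartet) -> ConfusionMatrix:
    """Recover integer cell counts from a published (N, prevalence, rate quartet) summary.

    Searches all integer matrices with ``round(N * prevalence)`` positives
    and N total for the one whose implied rates minimise the maximum
    absolute deviation from ``q`` (undefined components of ``q`` are
    ignored).  Ties break to the lexicographically smallest (tp, fp).
    """
    n_pos = int(round(n_total * prevalence))
    n_neg = n_total - n_pos
    if n_pos < 0 or n_neg < 0:
        raise ValueError("prevalence outside [0, 1]")
    if n_pos == 0 and q.tpr is not None and q.tpr > 0:
        raise ValueError("infeasible: zero positives but target TPR > 0")
    if n_neg == 0 and q.tnr is not None and q.tnr > 0:
        raise ValueError("infeasible: zero negatives but target TNR > 0")

    tp = np.arange(n_pos + 1, dtype=float)[:, None]
    fp = np.arange(n_neg + 1, dtype=float)[None, :]
    fn = n_pos - tp
    tn = n_neg - fp

    def dev(num, den, target):
        if target is None:
            return np.zeros((n_pos + 1, n_neg + 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        d = np.abs(r - target)
        return np.where(np.isnan(d), np.inf, d)

    worst = np.maximum.reduce(
        [
            dev(tp + 0 * fp, (tp + fn) + 0 * fp, q.tpr),
            dev(tn + 0 * tp, (tn + fp) + 0 * tp, q.tnr),
            dev(tp + 0 * fp, tp + fp, q.ppv),
            dev(tn + 0 * tp, tn + fn, q.npv),
        ]
    )
    best = worst.min()
    if not np.isfinite(best):
        raise ValueError("no feasible integer matrix matches the defined components")
    ties = np.argwhere(worst == best)
    i, j = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
    return ConfusionMatrix(tp=int(i), fp=int(j), fn=n_pos - int(i), tn=n_neg - int(j))


# ---------------------------------------------------------------------------
# bootstrap machinery


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate and percentile CI from a clustered case bootstrap.

    ``ci_lower <= ci_upper`` always holds; the plug-in estimate is not forced
    inside the interval (percentile CIs may exclude it under skew).
    ``redraws`` counts replicates that were redrawn because the metric was
    undefined (e.g. a resample with no positive calls).
    """

    estimate: float
    ci_lower: float
    ci_upper: float
    level: float
    B: int
    seed: int
    mode: str
    metric: str
    label: str
    redraws: int = 0
    replicates: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


MetricLike = Union[str, Callable[[ConfusionMatrix], float]]


def _metric_fn(metric: MetricLike) -> tuple:
    if callable(metric):
        return metric, getattr(metric, "__name__", "metric")
    try:
        return METRIC_REGISTRY[metric], metric
    except KeyError:
        known = ", ".join(sorted(METRIC_REGISTRY))
        raise KeyError(f"unknown metric {metric!r}; known metrics: {known}") from None


def _case_fractions(t: MrmcTable, modality) -> tuple:
    """Aligned per-case positive-call fractions, split by truth stratum.

    Returns (case index, fractions over positives, fractions over negatives),
    with case order fixed by sorted case id so that crossed-mode resampling
    can share indices across modalities.
    """
    calls = _positive_calls(t, modality).sort_index()
    truth = t.case_truth().loc[calls.index]
    frac = calls.mean(axis=1).to_numpy(dtype=float)
    mask = truth.to_numpy() == 1
    return calls.index, frac[mask], frac[~mask]


def _cm_from_fractions(a_pos: np.ndarray, a_neg: np.ndarray) -> ConfusionMatrix:
    tp, fp = float(a_pos.sum()), float(a_neg.sum())
    return ConfusionMatrix(tp=tp, fn=len(a_pos) - tp, fp=fp, tn=len(a_neg) - fp)


class _RedrawBudgetExceeded(RuntimeError):
    pass


def _bootstrap_replicates(stat_of_indices, n_pos, n_neg, B, rng, redraw_frac=0.01):
    """Draw B stratified case resamples, redrawing replicates whose statistic is undefined."""
    stats = np.empty(B)
    max_redraws = max(1, int(math.ceil(redraw_frac * B)))
    redraws = 0
    for b in range(B):
        while True:
            ip = rng.integers(0, n_pos, n_pos)
            ineg = rng.integers(0, n_neg, n_neg)
            try:
                stats[b] = stat_of_indices(ip, ineg)
                break
            except UndefinedMetricError:
                redraws += 1
                if redraws > max_redraws:
                    raise _RedrawBudgetExceeded(
                        f"more than {redraw_frac:.0%} of {B} bootstrap replicates "
                        "had an undefined metric; the data are too degenerate for "
                        "this metric/bootstrap combination"
                    ) from None
    return stats, redraws


def _percentile_ci(stats: np.ndarray, level: float) -> tuple:
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bootstrap_metric_ci(
    t: MrmcTable,
    modality,
    metric: MetricLike = "g4",
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    keep_replicates: bool = False,
) -> BootstrapResult:
    """Standalone percentile CI for a metric of one modality's reader-average matrix.

    Cases are resampled with replacement within the positive and negative
    truth strata (stratum sizes preserved, so prevalence is identical in
    every replicate); each resampled case carries all its readers' ratings.
    The metric is evaluated on the replicate's reader-average confusion
    matrix.
    """
    fn, name = _metric_fn(metric)
    _, a_pos, a_neg = _case_fractions(t, modality)
    if len(a_pos) == 0 or len(a_neg) == 0:
        raise ValueError("both truth strata must be non-empty")
    estimate = fn(_cm_from_fractions(a_pos, a_neg))
    rng = np.random.default_rng(seed)

    def stat(ip, ineg):
        return fn(_cm_from_fractions(a_pos[ip], a_neg[ineg]))

    stats, redraws = _bootstrap_replicates(stat, len(a_pos), len(a_neg), B, rng)
    lo, hi = _percentile_ci(stats, level)
    return BootstrapResult(
        estimate=float(estimate), ci_lower=lo, ci_upper=hi, level=level, B=B,
        seed=seed, mode="standalone", metric=name, label=str(modality),
        redraws=redraws, replicates=stats if keep_replicates else None,
    )


def bootstrap_difference_ci(
    t: MrmcTable,
    modality_a,
    modality_b,
    metric: MetricLike = "g4",
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    mode: str = "nested",
    keep_replicates: bool = False,
) -> BootstrapResult:
    """Percentile CI for metric(modality_a) - metric(modality_b).

    ``mode="nested"`` resamples case clusters independently per modality, as
    if readers/cases were not shared -- conservative (wider) when the
    modalities are positively correlated.  ``mode="crossed"`` applies one
    shared case resample to both modalities and requires both to cover the
    same case set.
    """
    if mode not in ("nested", "crossed"):
        raise ValueError("mode must be 'nested' or 'crossed'")
    fn, name = _metric_fn(metric)
    idx_a, apos, aneg = _case_fractions(t, modality_a)
    idx_b, bpos, bneg = _case_fractions(t, modality_b)
    if mode == "crossed" and not idx_a.equals(idx_b):
        raise ValueError("crossed mode requires identical case sets in both modalities")
    if min(len(apos), len(aneg), len(bpos), len(bneg)) == 0:
        raise ValueError("both truth strata must be non-empty in both modalities")
    estimate = fn(_cm_from_fractions(apos, aneg)) - fn(_cm_from_fractions(bpos, bneg))
    rng = np.random.default_rng(seed)

    if mode == "crossed":
        def stat(ip, ineg):
            return fn(_cm_from_fractions(apos[ip], aneg[ineg])) - fn(
                _cm_from_fractions(bpos[ip], bneg[ineg])
            )

        stats, redraws = _bootstrap_replicates(stat, len(apos), len(aneg), B, rng)
    else:
        def stat(ip, ineg):
            # second independent draw for modality b inside the same replicate
            jp = rng.integers(0, len(bpos), len(bpos))
            jn = rng.integers(0, len(bneg), len(bneg))
            return fn(_cm_from_fractions(apos[ip], aneg[ineg])) - fn(
                _cm_from_fractions(bpos[jp], bneg[jn])
            )

        stats, redraws = _bootstrap_replicates(stat, len(apos), len(aneg), B, rng)

    lo, hi = _percentile_ci(stats, level)
    return BootstrapResult(
        estimate=float(estimate), ci_lower=lo, ci_upper=hi, level=level, B=B,
        seed=seed, mode=mode, metric=name,
        label=f"{modality_a} - {modality_b}", redraws=redraws,
        replicates=stats if keep_replicates else None,
    )


# ---------------------------------------------------------------------------
# synthetic MRMC generator


def generate_synthetic_mrmc(
    n_cases: int = 663,
    prevalence: float = 0.074,
    n_readers: int = 10,
    reader_auroc_mean: float = 0.93,
    reader_auroc_sd: float = 0.02,
    modality_delta: float = 0.03,
    rating_levels: int = 6,
    seed: int = 0,
    case_effect_var: float = 0.5,
) -> MrmcTable:
    """Simulate a fully-crossed two-modality MRMC study with ordinal ratings.

    Emulates a reader study on a rare-prevalence cohort: truth is drawn with
    fixed class sizes ``round(n_cases * prevalence)``; each reader receives a
    per-reader AUROC from a truncated normal
    (``reader_auroc_mean`` +/- ``reader_auroc_sd``, truncated to
    [0.505, 0.995]); modality ``2`` shifts every reader's AUROC by
    ``modality_delta``.  Reader scores follow a binormal latent model with a
    shared per-case random effect (variance ``case_effect_var`` of the unit
    within-class variance) so cases are genuine clusters, and are binned into
    ``rating_levels`` ordinal levels whose middle cut sits at the midpoint
    between the class means; the table's positivity cut is
    ``rating_levels // 2 + 1`` (>= 4 on a 1-6 scale).
    """
    from scipy.stats import truncnorm

    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if rating_levels < 2:
        raise ValueError("rating_levels must be >= 2")
    if not 0 <= case_effect_var < 1:
        raise ValueError("case_effect_var must lie in [0, 1)")
    n_pos = int(round(n_cases * prevalence))
    n_neg = n_cases - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes round to zero; adjust n_cases or prevalence")

    rng = np.random.default_rng(seed)
    lo, hi = 0.505, 0.995
    a, b = (lo - reader_auroc_mean) / max(reader_auroc_sd, 1e-12), (
        hi - reader_auroc_mean
    ) / max(reader_auroc_sd, 1e-12)
    if reader_auroc_sd > 0:
        base_auroc = truncnorm.rvs(
            a, b, loc=reader_auroc_mean, scale=reader_auroc_sd,
            size=n_readers, random_state=rng,
        )
    else:
        base_auroc = np.full(n_readers, np.clip(reader_auroc_mean, lo, hi))

    truth = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    case_ids = np.arange(n_cases)
    z_case = rng.normal(0.0, 1.0, n_cases)  # shared across readers and modalities

    spacing = 0.8
    cuts = (np.arange(1, rating_levels) - rating_levels / 2.0) * spacing
    rows = []
    for modality in (1, 2):
        aurocs = np.clip(base_auroc + (modality_delta if modality == 2 else 0.0), lo, hi)
        for r in range(n_readers):
            d = auroc_to_cohens_d(float(aurocs[r]))
            noise = rng.normal(0.0, 1.0, n_cases)
            s = (
                d * (truth - 0.5)
                + math.sqrt(case_effect_var) * z_case
                + math.sqrt(1.0 - case_effect_var) * noise
            )
            # strict ">" at each cut, consistent with thresholding elsewhere
            rating = 1 + (s[:, None] > cuts[None, :]).sum(axis=1)
            rows.append(
                pd.DataFrame(
                    {
                        "modality": modality,
                        "reader": r + 1,
                        "case": case_ids,
                        "truth": truth,
                        "rating": rating,
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    return MrmcTable(data=data, positivity_cut=rating_levels // 2 + 1)


# ---------------------------------------------------------------------------
# model / results surface


class MrmcModel:
    """Balanced-metric-family analysis of an MRMC ratings table.

    Wraps an :class:`MrmcTable` and exposes :meth:`fit`, which runs the
    stratified clustered case bootstrap for each requested metric, per
    modality and (when two or more modalities are present) for each pairwise
    between-modality difference.

    Examples
    --------
    >>> table = generate_synthetic_mrmc(n_cases=120, prevalence=0.25, seed=7)
    >>> res = MrmcModel(table).fit(B=200, seed=7)
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, table: MrmcTable):
        self.table = table

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, positivity_cut: float = 4.0) -> "MrmcModel":
        return cls(MrmcTable(data=data, positivity_cut=positivity_cut))

    @classmethod
    def from_csv(cls, path, positivity_cut: float = 4.0) -> "MrmcModel":
        return cls(MrmcTable.from_csv(path, positivity_cut=positivity_cut))

    def reader_average(self, modality) -> ConfusionMatrix:
        return reader_average_cm(self.table, modality)

    def fit(
        self,
        metrics: Sequence[MetricLike] = ("g4", "p4", "mcc_scaled"),
        B: int = 2000,
        level: float = 0.95,
        seed: int = 0,
        mode: str = "nested",
    ) -> "MrmcResults":
        """Bootstrap standalone and between-modality inference.

        ``mode`` governs the difference CIs only; standalone CIs always use
        the stratified clustered resample of the single modality.
        """
        results = []
        mods = self.table.modalities
        ss = np.random.SeedSequence(seed)
        seeds = iter(int(s) for s in ss.generate_state(len(mods) * len(metrics) * 4) >> 1)
        for m in mods:
            for metric in metrics:
                results.append(
                    bootstrap_metric_ci(self.table, m, metric=metric, B=B, level=level,
                                        seed=next(seeds))
                )
        for m_a, m_b in itertools.combinations(mods, 2):
            for metric in metrics:
                results.append(
                    bootstrap_difference_ci(self.table, m_a, m_b, metric=metric, B=B,
                                            level=level, seed=next(seeds), mode=mode)
                )
        return MrmcResults(model=self, results=results, B=B, level=level, seed=seed, mode=mode)


@dataclass
class MrmcResults:
    """Container for fitted MRMC bootstrap results.

    ``results`` holds one :class:`BootstrapResult` per (modality-or-contrast,
    metric); :meth:`frame` tabulates them and :meth:`summary` renders the
    table with percentages to one decimal.
    """

    model: MrmcModel
    results: list
    B: int
    level: float
    seed: int
    mode: str

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "modality_or_contrast": r.label,
                "metric": r.metric,
                "estimate": r.estimate,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "level": r.level,
                "B": r.B,
                "seed": r.seed,
                "mode": r.mode,
                "redraws": r.redraws,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def get(self, label, metric: str) -> BootstrapResult:
        for r in self.results:
            if r.label == str(label) and r.metric == metric:
                return r
        raise KeyError(f"no result for ({label!r}, {metric!r})")

    def summary(self) -> str:
        df = self.frame()
        prev = self.model.table.prevalence
        lines = [
            "MRMC balanced-metric-family bootstrap",
            f"  cases: {len(self.model.table.case_truth())}  "
            f"prevalence: {100 * prev:.1f}%  readers: {len(self.model.table.readers)}",
            f"  B = {self.B}  level = {self.level:.0%}  difference mode = {self.mode}  "
            f"seed = {self.seed}",
            "",
            f"  {'modality/contrast':<22}{'metric':<12}{'estimate':>9}  {'CI':>18}",
        ]
        for _, row in df.iterrows():
            ci = f"({100 * row.ci_lower:.1f}%, {100 * row.ci_upper:.1f}%)"
            lines.append(
                f"  {row.modality_or_contrast:<22}{row.metric:<12}"
                f"{100 * row.estimate:>8.1f}%  {ci:>18}"
            )
        return "\n".join(lines)
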