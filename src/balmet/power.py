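"""Simulation-based power and sample size for G4 benchmark tests.

The test of interest declares success when the one-sided lower percentile
bootstrap confidence bound for G4 exceeds a fixed benchmark (e.g. from
:func:`balmet.binormal.rule_of_thumb`).  Power is estimated by Monte Carlo:
simulate many studies from the binormal model at the hypothesised regime
(true AUROC, prevalence, n cases), run the stratified case bootstrap within
each, and count the fraction that pass.

For a single classifier with fixed predictions, resampling cases with
replacement within each truth stratum is distributionally identical to
drawing ``tp* ~ Binomial(n+, tp/n+)`` and ``fp* ~ Binomial(n-, fp/n-)``;
the inner bootstrap uses that exact equivalence so the outer Monte Carlo
loop stays cheap.  Replicates on which G4 is undefined (no positive or no
negative calls at all) are redrawn and counted, mirroring the MRMC
bootstrap's redraw policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binormal import SimulationConfig, simulate_scoreset
from .roc import threshold_classify

__all__ = ["PowerConfig", "PowerResult", "SampleSizeResult", "estimate_power", "required_n"]


@dataclass(frozen=True)
class PowerConfig:
    """Regime and test configuration for a G4 benchmark power study.

    Parameters
    ----------
    true_auroc : float
        Discrimination of the simulated classifier, in [0.5, 1).
    prevalence : float
        Minority-class prevalence of the simulated cohort.
    n_cases : int
        Cases per simulated study.
    benchmark : float
        Fixed G4 benchmark the lower confidence bound must exceed.
    alpha : float
        Test size; the one-sided lower bound is the alpha quantile of the
        bootstrap distribution (alpha/2 when ``two_sided``).
    n_replicates : int
        Simulated studies in the outer Monte Carlo loop.
    B_inner : int
        Bootstrap replicates per simulated study; 500 by default, since
        power estimation tolerates coarser quantiles than reporting a CI.
    threshold : float
        Probability threshold for positive calls.
    """

    true_auroc: float
    prevalence: float
    n_cases: int
    benchmark: float
    alpha: float = 0.05
    n_replicates: int = 200
    B_inner: int = 500
    threshold: float = 0.5
    two_sided: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.benchmark < 1.0:
            raise ValueError("benchmark must lie in (0, 1)")
        # domain checks for the simulation regime
        SimulationConfig(
            nominal_auroc=self.true_auroc, prevalence=self.prevalence,
            n=self.n_cases, threshold=self.threshold, seed=0,
        )


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    n: int
    alpha: float
    benchmark: float
    seed: int
    n_replicates: int
    mean_lower_bound: float


@dataclass(frozen=True)
class SampleSizeResult:
    n: int
    target_power: float
    achieved_power: float
    trace: tuple  # ((n, power), ...) in evaluation order


def _g4_vec(tp, fp, n_pos, n_neg):
    """Vectorised G4 over integer cell arrays; NaN flags undefined marginals."""
    fn = n_pos - tp
    tn = n_neg - fp
    pred_pos = tp + fp
    pred_neg = tn + fn
    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = tp / n_pos
        tnr = tn / n_neg
        ppv = np.where(pred_pos > 0, tp / np.where(pred_pos > 0, pred_pos, 1), np.nan)
        npv = np.where(pred_neg > 0, tn / np.where(pred_neg > 0, pred_neg, 1), np.nan)
    return (tpr * tnr * ppv * npv) ** 0.25


def _bootstrap_lower_bound(cm, q_level, B, rng, redraw_frac=0.01):
    """q_level quantile of the stratified case-bootstrap G4 distribution."""
    n_pos = int(cm.tp + cm.fn)
    n_neg = int(cm.tn + cm.fp)
    tp = rng.binomial(n_pos, cm.tp / n_pos, B)
    fp = rng.binomial(n_neg, cm.fp / n_neg, B)
    g = _g4_vec(tp, fp, n_pos, n_neg)
    redraws = 0
    max_redraws = max(1, int(math.ceil(redraw_frac * B)))
    bad = np.isnan(g)
    while bad.any():
        redraws += int(bad.sum())
        if redraws > max_redraws:
            raise RuntimeError(
                f"more than {redraw_frac:.0%} of inner bootstrap replicates were undefined"
            )
        k = int(bad.sum())
        tp[bad] = rng.binomial(n_pos, cm.tp / n_pos, k)
        fp[bad] = rng.binomial(n_neg, cm.fp / n_neg, k)
        g = _g4_vec(tp, fp, n_pos, n_neg)
        bad = np.isnan(g)
    return float(np.quantile(g, q_level))


def estimate_power(cfg: PowerConfig) -> PowerResult:
    """Monte Carlo power of the one-sided G4 benchmark test.

    Returns the fraction of simulated studies whose bootstrap lower
    confidence bound exceeds ``cfg.benchmark``, together with the binomial
    Monte Carlo standard error of that fraction.
    """
    q_level = cfg.alpha / 2.0 if cfg.two_sided else cfg.alpha
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(2 * cfg.n_replicates) >> 1
    passes = 0
    lb_sum = 0.0
    for r in range(cfg.n_replicates):
        sim = SimulationConfig(
            nominal_auroc=cfg.true_auroc, prevalence=cfg.prevalence,
            n=cfg.n_cases, threshold=cfg.threshold, seed=int(seeds[2 * r]),
        )
        cm = threshold_classify(simulate_scoreset(sim), cfg.threshold)
        rng = np.random.default_rng(int(seeds[2 * r + 1]))
        lb = _bootstrap_lower_bound(cm, q_level, cfg.B_inner, rng)
        lb_sum += lb
        if lb > cfg.benchmark:
            passes += 1
    power = passes / cfg.n_replicates
    mc_se = math.sqrt(max(power * (1.0 - power), 1.0 / cfg.n_replicates) / cfg.n_replicates)
    return PowerResult(
        power=power, mc_se=mc_se, n=cfg.n_cases, alpha=cfg.alpha,
        benchmark=cfg.benchmark, seed=cfg.seed, n_replicates=cfg.n_replicates,
        mean_lower_bound=lb_sum / cfg.n_replicates,
    )


def required_n(
    cfg: PowerConfig,
    target_power: float,
    n_start: int = 25,
    n_cap: int = 50_000,
) -> SampleSizeResult:
    """Smallest case count whose estimated power reaches ``target_power``.

    Doubles ``n`` from ``n_start`` until the target is met, then bisects.
    Every power evaluation reuses ``cfg.seed`` (common random numbers), which
    keeps the empirical power curve monotone enough for bisection to be
    meaningful at moderate ``n_replicates``.  ``cfg.n_cases`` is ignored.
    """
    if not cfg.alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")

    trace = []

    def power_at(n: int) -> float:
        c = PowerConfig(
            true_auroc=cfg.true_auroc, prevalence=cfg.prevalence, n_cases=n,
            benchmark=cfg.benchmark, alpha=cfg.alpha,
            n_replicates=cfg.n_replicates, B_inner=cfg.B_inner,
            threshold=cfg.threshold, two_sided=cfg.two_sided, seed=cfg.seed,
        )
        p = estimate_power(c).power
        trace.append((n, p))
        return p

    # ensure the class sizes are non-degenerate at the starting n
    min_n = max(n_start, int(math.ceil(1.0 / min(cfg.prevalence, 1 - cfg.prevalence))) + 1)
    n = min_n
    p = power_at(n)
    while p < target_power:
        if n >= n_cap:
            raise RuntimeError(
                f"target power {target_power} not reached by n = {n_cap} "
                f"(last estimate {p:.3f})"
            )
        n = min(2 * n, n_cap)
        p = power_at(n)
    lo, hi = (trace[-2][0], n) if len(trace) >= 2 and trace[-2][1] < target_power else (min_n, n)
    achieved = p
    while hi - lo > max(1, lo // 20):  # ~5% resolution on n
        mid = (lo + hi) // 2
        p_mid = power_at(mid)
        if p_mid >= target_power:
            hi, achieved = mid, p_mid
        else:
            lo = mid
    return SampleSizeResult(
        n=hi, target_power=target_power, achieved_power=achieved, trace=tuple(trace)
    )
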