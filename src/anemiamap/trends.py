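"""Annualized rates of change, logit-space projection, and GNT attainment.

The annualized rate of change (AROC) between adjacent years is the
difference of logit prevalences, AROC_{a,t} = logit(p_{a,t}) −
logit(p_{a,t−1}); a weighted average with weights W_t ∝ (t − 2000)^γ
(recent years up-weighted, Σ W_t = 1) gives each unit's AROC, which is then
applied in logit space: Proj = logit⁻¹(logit(p_last) + AROC·k).  Attainment
of the WHO Global Nutrition Target (a 50% reduction in anemia among WRA
relative to the 2012 baseline) is the fraction of paired posterior draws
whose projection meets the reduced baseline.

A literal variant of the pairwise rate, logit(p_t / p_{t−1}), is available
behind ``use_printed_formula`` for audit; it is positive for declining
prevalence and is not on the scale the projection equation requires, so the
logit-difference is the default.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pairwise_aroc",
    "aroc_weights",
    "weighted_aroc",
    "project",
    "gnt_probability",
    "classify_attainment",
]

EPS = 1e-6


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def pairwise_aroc(series: np.ndarray, use_printed_formula: bool = False) -> np.ndarray:
    """AROC between adjacent years along the last axis.

    ``series`` holds prevalences for consecutive years; boundary values are
    nudged into (0, 1) by EPS.  Output has one fewer entry on the last axis.
    """
    p = np.clip(np.asarray(series, dtype=float), EPS, 1 - EPS)
    if p.shape[-1] < 2:
        raise ValueError("need at least two consecutive years")
    if use_printed_formula:
        return _logit(np.clip(p[..., 1:] / p[..., :-1], EPS, 1 - EPS))
    lp = _logit(p)
    return lp[..., 1:] - lp[..., :-1]


def aroc_weights(years: np.ndarray, aroc_gamma: float, origin_year: int = 2000) -> np.ndarray:
    """W_t = (t − origin)^γ / Σ (t − origin)^γ over the AROC years."""
    if aroc_gamma < 0:
        raise ValueError("aroc_gamma must be >= 0")
    t = np.asarray(years, dtype=float) - origin_year
    if np.any(t <= 0):
        raise ValueError("AROC years must be after the origin year")
    w = t**aroc_gamma
    return w / w.sum()


def weighted_aroc(pairwise: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of the pairwise AROCs along the last axis."""
    pairwise = np.asarray(pairwise, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if pairwise.shape[-1] != len(weights):
        raise ValueError("weights not aligned with pairwise AROCs")
    return pairwise @ weights


def project(p_last: np.ndarray, aroc: np.ndarray, horizon_years: int) -> np.ndarray:
    """logit⁻¹(logit(p_last) + AROC × k); always inside (0, 1)."""
    p = np.clip(np.asarray(p_last, dtype=float), EPS, 1 - EPS)
    return _inv_logit(_logit(p) + np.asarray(aroc, dtype=float) * horizon_years)


def gnt_probability(
    projection_draws: np.ndarray,
    baseline_draws: np.ndarray,
    reduction: float = 0.5,
) -> float:
    """Fraction of paired draws with projection ≤ (1 − reduction) × baseline."""
    proj = np.asarray(projection_draws, dtype=float)
    base = np.asarray(baseline_draws, dtype=float)
    if proj.shape != base.shape:
        raise ValueError("projection and baseline draws must be paired")
    return float(np.mean(proj <= (1.0 - reduction) * base))


def classify_attainment(probability: float) -> str:
    """<5% low, >95% high posterior probability; otherwise uncertain."""
    if probability < 0.05:
        return "low"
    if probability > 0.95:
        return "high"
    return "uncertain"
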