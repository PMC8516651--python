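"""Spatially stratified cross-validation and predictive-validity metrics.

Folds come from a modified bi-tree: two-dimensional space is recursively
partitioned, alternating split axes (longitude first), at the weighted
median of the data sample sizes, until a further split would push a leaf
below the minimum sample size (500 by convention) or the leaf is already at
the target size.  Leaves are allocated to five folds balancing total sample
size.  Metrics — mean error, RMSE, coefficient of variation (100·sd/mean),
95% predictive-interval coverage and Pearson correlation — are computed on
sample-size-weighted admin-level aggregates of held-out observations.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialPartition",
    "bitree_partition",
    "assign_folds",
    "cross_validate",
    "validation_metrics",
]


@dataclasses.dataclass
class SpatialPartition:
    """Bi-tree leaves: per-point leaf labels plus the split tree."""

    leaf_of_point: np.ndarray
    leaf_sizes: dict[int, float]
    tree: dict

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_sizes)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cum, cum[-1] / 2.0)])


def bitree_partition(
    points: pd.DataFrame,
    target_size: float,
    min_size: float = 500.0,
) -> SpatialPartition:
    """Recursive alternating-axis partition on weighted sample-size medians.

    ``points`` needs columns lon, lat, size.  The first split is on
    longitude; points exactly at the weighted median go to the lower side.
    A node splits only if its total exceeds ``target_size`` and both
    children would keep at least ``min_size``.
    """
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    size = points["size"].to_numpy(float)
    if size.sum() < min_size:
        raise ValueError("total sample size below the minimum leaf size")

    leaf_of_point = np.full(len(points), -1, dtype=int)
    leaf_sizes: dict[int, float] = {}
    counter = [0]

    def split(idx: np.ndarray, axis: int) -> dict:
        total = float(size[idx].sum())
        coords = lon[idx] if axis == 0 else lat[idx]
        can_try = total > target_size and total >= 2 * min_size
        for ax in ((axis, 1 - axis) if can_try else ()):
            c = lon[idx] if ax == 0 else lat[idx]
            if np.all(c == c[0]):
                continue  # degenerate on this axis; try the other
            med = _weighted_median(c, size[idx])
            lower = c <= med
            lo_tot, hi_tot = size[idx][lower].sum(), size[idx][~lower].sum()
            if lower.all() or (~lower).all():
                continue
            if lo_tot < min_size or hi_tot < min_size:
                continue
            return {
                "axis": ax,
                "split": med,
                "low": split(idx[lower], 1 - ax),
                "high": split(idx[~lower], 1 - ax),
            }
        if can_try:
            logger.warning("bi-tree leaf of size %.0f could not be split", total)
        leaf = counter[0]
        counter[0] += 1
        leaf_of_point[idx] = leaf
        leaf_sizes[leaf] = total
        return {"leaf": leaf, "size": total}

    # evaluate on lexicographically ordered points so the partition is
    # invariant to input order
    order = np.lexsort((lat, lon))
    tree = split(order, axis=0)
    return SpatialPartition(leaf_of_point=leaf_of_point, leaf_sizes=leaf_sizes, tree=tree)


def assign_folds(partition: SpatialPartition, k: int = 5, seed: int = 0) -> np.ndarray:
    """Greedy largest-first allocation of leaves to k folds of similar size.

    Returns the fold label per point.  Deterministic given the partition
    (and therefore under the pipeline seed).
    """
    if partition.n_leaves < k:
        raise ValueError(f"need at least {k} leaves, got {partition.n_leaves}")
    leaves = sorted(partition.leaf_sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    fold_tot = np.zeros(k)
    fold_of_leaf: dict[int, int] = {}
    for leaf, total in leaves:
        f = int(np.argmin(fold_tot))
        fold_of_leaf[leaf] = f
        fold_tot[f] += total
    return np.array([fold_of_leaf[l] for l in partition.leaf_of_point])


def cross_validate(fit_predict, observations: pd.DataFrame, folds: np.ndarray):
    """Run the hold-one-fold-out loop.

    ``fit_predict(train_df, test_df, fold)`` returns draw-level predictions
    (D, n_test) for the held-out observations.  Returns the out-of-sample
    draw matrix aligned to ``observations`` row order, covering every
    observation exactly once.
    """
    folds = np.asarray(folds)
    oos: np.ndarray | None = None
    for f in np.unique(folds):
        train = observations.loc[folds != f]
        test = observations.loc[folds == f]
        try:
            pred = np.asarray(fit_predict(train, test, int(f)))
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"cross-validation fold {f} failed") from err
        if oos is None:
            oos = np.empty((pred.shape[0], len(observations)))
        oos[:, folds == f] = pred
    return oos


def validation_metrics(
    observations: pd.DataFrame,
    predicted_draws: np.ndarray,
    unit_labels: np.ndarray,
    predicted_counts: np.ndarray | None = None,
) -> dict[str, float]:
    """Admin-level ME, RMSE, CoV, 95% coverage, correlation.

    Observed cluster proportions and predicted draws are aggregated to the
    given admin units with effective-sample-size weights before scoring.
    Coverage uses ``predicted_counts`` (draws of simulated observed counts,
    capturing binomial noise) when supplied, else the prevalence draws.
    Returns NaNs when fewer than two units are available.
    """
    y = observations["anemic"].to_numpy(float)
    n = observations["N"].to_numpy(float)
    w = observations["weight"].to_numpy(float) * n
    units = np.unique(unit_labels)
    if len(units) < 2:
        return {k: float("nan") for k in ("me", "rmse", "cov", "coverage", "correlation")}

    obs_agg = np.empty(len(units))
    pred_agg = np.empty((predicted_draws.shape[0], len(units)))
    band_agg = np.empty_like(pred_agg)
    band_source = predicted_counts if predicted_counts is not None else predicted_draws
    for i, u in enumerate(units):
        sel = unit_labels == u
        ww = w[sel] / w[sel].sum()
        obs_agg[i] = np.sum(ww * y[sel] / n[sel])
        pred_agg[:, i] = predicted_draws[:, sel] @ ww
        band_agg[:, i] = band_source[:, sel] @ ww

    pred_mean = pred_agg.mean(axis=0)
    err = obs_agg - pred_mean
    lo = np.quantile(band_agg, 0.025, axis=0)
    hi = np.quantile(band_agg, 0.975, axis=0)
    return {
        "me": float(err.mean()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "cov": float(100.0 * pred_mean.std() / pred_mean.mean()),
        "coverage": float(np.mean((obs_agg >= lo) & (obs_agg <= hi))),
        "correlation": float(np.corrcoef(obs_agg, pred_mean)[0, 1]),
    }
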