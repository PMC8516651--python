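"""Post-estimation: masking, admin aggregation, counts, YLDs, burden classes.

Grid-cell prevalence draws are masked (sparsely populated or barren cells),
aggregated population-weighted to admin 0/1/2 units, turned into affected
counts of women of reproductive age (WRA), and into years lived with
disability (YLDs) via severity-specific disability weights.  All operations
are draw-wise so uncertainty propagates unchanged.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "DisabilityWeights",
    "apply_mask",
    "aggregate_to_admin",
    "summarize_aggregates",
    "compute_counts",
    "compute_ylds",
    "classify_public_health_problem",
    "inequality_summaries",
]

INDICATORS = ("overall", "mild", "moderate", "severe")


@dataclasses.dataclass(frozen=True)
class DisabilityWeights:
    """GBD-convention disability weights per severity level."""

    mild: float = 0.004
    moderate: float = 0.052
    severe: float = 0.149

    def __post_init__(self) -> None:
        if not 0 <= self.mild < self.moderate < self.severe <= 1:
            raise ValueError("disability weights must satisfy mild < moderate < severe")

    def as_dict(self) -> dict[str, float]:
        return {"mild": self.mild, "moderate": self.moderate, "severe": self.severe}


def apply_mask(
    population: np.ndarray,
    barren: np.ndarray,
    grid: GridSpec,
    threshold_per_km2: float = 10.0,
) -> np.ndarray:
    """Boolean keep-mask: True where estimates are reported.

    Cells with fewer than ``threshold_per_km2`` persons per km² (the 1×1-km
    threshold scaled to the cell area) or classified barren are masked out.
    """
    if population.shape != (grid.n_rows, grid.n_cols) or barren.shape != population.shape:
        raise ValueError("rasters not aligned to the grid")
    min_pop = threshold_per_km2 * grid.cell_area_km2
    keep = (population >= min_pop) & ~barren.astype(bool)
    logger.info("masking %d of %d cells", int((~keep).sum()), keep.size)
    return keep


def aggregate_to_admin(
    draws: xr.Dataset,
    population: np.ndarray,
    admin_map: np.ndarray,
    keep_mask: np.ndarray | None = None,
) -> xr.Dataset:
    """Population-weighted unit aggregates, per draw and year.

    Returns a Dataset with dims (indicator-named vars; draw, year, unit).
    Units whose unmasked population is zero are dropped with a warning.
    """
    keep = np.ones_like(admin_map, dtype=bool) if keep_mask is None else keep_mask
    pop = np.where(keep, population, 0.0).ravel()
    units = np.unique(admin_map)
    flat_map = admin_map.ravel()
    weights = []
    valid_units = []
    for u in units:
        w = np.where(flat_map == u, pop, 0.0)
        if w.sum() <= 0:
            logger.warning("admin unit %s has zero unmasked population", u)
            continue
        weights.append(w / w.sum())
        valid_units.append(int(u))
    if not valid_units:
        raise ValueError("no admin unit has unmasked population")
    W = np.array(weights)  # (n_units, n_cells)

    out = {}
    for name, da in draws.data_vars.items():
        arr = da.values  # (D, Y, R, C)
        D, Y = arr.shape[:2]
        flat = arr.reshape(D, Y, -1)
        out[name] = (("draw", "year", "unit"), np.einsum("dyc,uc->dyu", flat, W))
    return xr.Dataset(
        out,
        coords={
            "draw": draws["draw"].values,
            "year": draws["year"].values,
            "unit": valid_units,
        },
    )


def unit_population(
    population: np.ndarray,
    admin_map: np.ndarray,
    keep_mask: np.ndarray | None = None,
    wra_fraction: float = 1.0,
) -> pd.Series:
    """Unmasked (WRA) population per admin unit."""
    keep = np.ones_like(admin_map, dtype=bool) if keep_mask is None else keep_mask
    pop = np.where(keep, population, 0.0) * wra_fraction
    totals = {
        int(u): float(pop[admin_map == u].sum()) for u in np.unique(admin_map)
    }
    return pd.Series(totals, name="population")


def summarize_aggregates(aggregates: xr.Dataset, level: int) -> pd.DataFrame:
    """Mean and central 95% interval per unit-year-indicator."""
    rows = []
    for name, da in aggregates.data_vars.items():
        mean = da.mean("draw")
        lo = da.quantile(0.025, "draw")
        hi = da.quantile(0.975, "draw")
        for u in aggregates["unit"].values:
            for y in aggregates["year"].values:
                rows.append(
                    {
                        "level": level,
                        "unit": int(u),
                        "year": int(y),
                        "indicator": name,
                        "mean": float(mean.sel(unit=u, year=y)),
                        "lower": float(lo.sel(unit=u, year=y)),
                        "upper": float(hi.sel(unit=u, year=y)),
                    }
                )
    return pd.DataFrame(rows)


def compute_counts(aggregates: xr.Dataset, unit_wra: pd.Series) -> xr.Dataset:
    """Affected WRA counts: prevalence × unit WRA population, draw-wise."""
    wra = xr.DataArray(
        [unit_wra[int(u)] for u in aggregates["unit"].values],
        dims=("unit",),
        coords={"unit": aggregates["unit"].values},
    )
    return aggregates * wra


def compute_ylds(counts: xr.Dataset, dw: DisabilityWeights) -> xr.Dataset:
    """YLDs per severity plus their total, draw-wise."""
    out = {}
    for sev, weight in dw.as_dict().items():
        if sev in counts:
            out[sev] = counts[sev] * weight
    total = sum(out.values())
    out["total"] = total
    return xr.Dataset(out)


def classify_public_health_problem(prevalence) -> np.ndarray:
    """WHO burden class from overall anemia prevalence.

    <5% none; 5–19.9% low; 20–39.9% medium; ≥40% high.
    """
    p = np.asarray(prevalence, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalence must be in [0, 1]")
    return np.select(
        [p < 0.05, p < 0.20, p < 0.40], ["none", "low", "medium"], default="high"
    ).astype(object)


def inequality_summaries(
    admin2_means: pd.DataFrame,
    national_means: pd.DataFrame,
) -> pd.DataFrame:
    """Within-country absolute and relative subnational inequality.

    ``admin2_means``: columns country, unit, mean (overall anemia).
    ``national_means``: columns country, mean (population-weighted national
    mean, consistent with :func:`aggregate_to_admin`).  Countries with fewer
    than two units are skipped.
    """
    rows = []
    nat = national_means.set_index("country")["mean"]
    for country, grp in admin2_means.groupby("country"):
        if len(grp) < 2:
            continue
        lo, hi = float(grp["mean"].min()), float(grp["mean"].max())
        rows.append(
            {
                "country": country,
                "min": lo,
                "max": hi,
                "absolute_range": hi - lo,
                "fold_difference": hi / lo if lo > 0 else np.nan,
                "ratio_min": lo / nat[country],
                "ratio_max": hi / nat[country],
            }
        )
    return pd.DataFrame(rows)
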