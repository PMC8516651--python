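"""Hemoglobin adjustment, WHO severity classification, and cluster prep.

Individual-level hemoglobin (g/dl) is adjusted for residential elevation and
smoking before WHO severity thresholding.  Women 15-49 are then collapsed to
cluster-level binomial totals (N sampled; counts anemic / mild / moderate /
severe), and polygon-referenced (areal) records are resampled to
population-weighted pseudo-point clusters whose weights sum to one.

Severity bands are closed on the left, open on the right: for non-pregnant
women mild is [11.0, 12.0), moderate [8.0, 11.0), severe < 8.0 g/dl; for
pregnant women the bands shift down by 1 g/dl.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PROVENANCES",
    "CATEGORIES",
    "AdjustmentTables",
    "SeverityThresholds",
    "PointsPerCellRule",
    "adjust_hemoglobin",
    "classify_severity",
    "collapse_to_clusters",
    "resample_polygon",
]

PROVENANCES = ("raw", "smoking_adjusted", "elevation_adjusted", "fully_adjusted")
CATEGORIES = ("non_anemic", "mild", "moderate", "severe")

CLUSTER_COLUMNS = [
    "cluster_id", "lon", "lat", "year", "weight",
    "N", "anemic", "mild", "moderate", "severe",
]


@dataclasses.dataclass(frozen=True)
class AdjustmentTables:
    """Elevation and smoking decrements subtracted from measured hemoglobin.

    ``elevation_bins`` maps the lower edge of each contiguous elevation band
    (meters) to a decrement (g/dl); the first band must start at 0 m with
    decrement 0.  Defaults follow the WHO/CDC convention but are config data
    and can be overridden.
    """

    elevation_bins: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (1000.0, 0.2),
        (1500.0, 0.5),
        (2000.0, 0.8),
        (2500.0, 1.3),
        (3000.0, 1.9),
        (3500.0, 2.7),
        (4000.0, 3.5),
        (4500.0, 4.5),
    )
    smoking_decrement: float = 0.3

    def __post_init__(self) -> None:
        edges = [e for e, _ in self.elevation_bins]
        decs = [d for _, d in self.elevation_bins]
        if edges[0] != 0.0 or decs[0] != 0.0:
            raise ValueError("first elevation bin must start at 0 m with decrement 0")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("elevation bin edges must increase")
        if any(d < 0 for d in decs) or self.smoking_decrement < 0:
            raise ValueError("decrements must be non-negative")

    def elevation_decrement(self, elevation) -> np.ndarray:
        edges = np.array([e for e, _ in self.elevation_bins])
        decs = np.array([d for _, d in self.elevation_bins])
        idx = np.searchsorted(edges, np.asarray(elevation, dtype=float), side="right") - 1
        return decs[np.clip(idx, 0, len(decs) - 1)]


@dataclasses.dataclass(frozen=True)
class SeverityThresholds:
    """WHO hemoglobin cutoffs (g/dl) by pregnancy status.

    Each triple is (severe_below, moderate_below, overall_cutoff): severe is
    hb < severe_below, moderate is [severe_below, moderate_below), mild is
    [moderate_below, overall_cutoff), non-anemic is hb >= overall_cutoff.
    """

    non_pregnant: tuple[float, float, float] = (8.0, 11.0, 12.0)
    pregnant: tuple[float, float, float] = (7.0, 10.0, 11.0)

    def __post_init__(self) -> None:
        for cuts in (self.non_pregnant, self.pregnant):
            if not (0 < cuts[0] < cuts[1] < cuts[2]):
                raise ValueError("cutoffs must satisfy severe < moderate < overall")

    def cuts(self, pregnant) -> np.ndarray:
        """(n, 3) cutoff rows matching each record's pregnancy status."""
        pregnant = np.asarray(pregnant, dtype=bool)
        table = np.array([self.non_pregnant, self.pregnant])
        return table[pregnant.astype(int)]


def adjust_hemoglobin(
    raw_hb,
    elevation,
    smoker,
    provenance,
    tables: AdjustmentTables,
) -> np.ndarray:
    """Apply the elevation/smoking decrements not already applied upstream.

    ``provenance`` (scalar or array) says which adjustments the source data
    already carry; fully adjusted inputs pass through unchanged.  Negative
    results are clamped to 0.1 g/dl with a warning.
    """
    hb = np.array(raw_hb, dtype=float)
    prov = np.broadcast_to(np.asarray(provenance, dtype=object), hb.shape).ravel()
    unknown = set(prov) - set(PROVENANCES)
    if unknown:
        raise ValueError(f"unknown hemoglobin provenance: {sorted(unknown)}")
    prov = prov.reshape(hb.shape)

    needs_elev = (prov == "raw") | (prov == "smoking_adjusted")
    needs_smoke = (prov == "raw") | (prov == "elevation_adjusted")
    elev_dec = tables.elevation_decrement(np.broadcast_to(elevation, hb.shape))
    smoke = np.broadcast_to(np.asarray(smoker, dtype=bool), hb.shape)

    adjusted = (
        hb
        - np.where(needs_elev, elev_dec, 0.0)
        - np.where(needs_smoke & smoke, tables.smoking_decrement, 0.0)
    )
    bad = adjusted <= 0
    if np.any(bad):
        logger.warning(
            "%d adjusted hemoglobin values <= 0 clamped to 0.1 g/dl", int(bad.sum())
        )
        adjusted = np.where(bad, 0.1, adjusted)
    return adjusted


def classify_severity(adjusted_hb, pregnant, thresholds: SeverityThresholds) -> np.ndarray:
    """WHO severity category for each adjusted hemoglobin value."""
    hb = np.asarray(adjusted_hb, dtype=float)
    if np.any(hb <= 0):
        raise ValueError("adjusted hemoglobin must be positive")
    cuts = thresholds.cuts(np.broadcast_to(pregnant, hb.shape))
    severe_below, moderate_below, overall = cuts[..., 0], cuts[..., 1], cuts[..., 2]
    out = np.select(
        [hb < severe_below, hb < moderate_below, hb < overall],
        ["severe", "moderate", "mild"],
        default="non_anemic",
    ).astype(object)
    return out.item() if out.ndim == 0 else out


def collapse_to_clusters(
    records: pd.DataFrame,
    tables: AdjustmentTables | None = None,
    thresholds: SeverityThresholds | None = None,
) -> pd.DataFrame:
    """Collapse woman-level records to cluster-year binomial observations.

    Records with a ``category`` column are counted directly (category-only
    sources); otherwise hemoglobin is adjusted and thresholded here.  The age
    filter 15-49 (inclusive) is applied first.  Output rows carry weight 1
    (directly geolocated clusters).
    """
    if records.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    df = records.copy()
    if "age" in df.columns:
        df = df[(df["age"] >= 15) & (df["age"] <= 49)]
    if df.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)

    if "category" not in df.columns:
        tables = tables or AdjustmentTables()
        thresholds = thresholds or SeverityThresholds()
        adj = adjust_hemoglobin(
            df["raw_hb"], df["elevation"], df["smoker"], df["provenance"], tables
        )
        df = df.assign(category=classify_severity(adj, df["pregnant"], thresholds))

    for cat in CATEGORIES[1:]:
        df[cat] = (df["category"] == cat).astype(int)
    grouped = df.groupby(["cluster_id", "year"], sort=True).agg(
        lon=("lon", "first"),
        lat=("lat", "first"),
        N=("category", "size"),
        mild=("mild", "sum"),
        moderate=("moderate", "sum"),
        severe=("severe", "sum"),
    )
    grouped = grouped.reset_index()
    grouped["anemic"] = grouped["mild"] + grouped["moderate"] + grouped["severe"]
    grouped["weight"] = 1.0
    empty = grouped["N"] == 0
    if empty.any():
        logger.info("dropping %d empty cluster-years", int(empty.sum()))
        grouped = grouped[~empty]
    return grouped[CLUSTER_COLUMNS].reset_index(drop=True)


@dataclasses.dataclass(frozen=True)
class PointsPerCellRule:
    """How many pseudo-points an areal record is resampled to.

    One point per ``cells_per_point`` grid cells intersecting the polygon,
    clipped to [min_points, max_points].
    """

    cells_per_point: int = 10
    min_points: int = 1
    max_points: int = 100

    def n_points(self, n_cells: int) -> int:
        return int(np.clip(int(np.ceil(n_cells / self.cells_per_point)),
                           self.min_points, self.max_points))


def polygon_cells(polygon, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of grid cells whose centres fall inside the polygon."""
    from shapely.geometry import Point
    from shapely.prepared import prep

    lon, lat = grid.cell_centers()
    prepared = prep(polygon.buffer(1e-9))
    inside = np.array(
        [prepared.contains(Point(x, y)) for x, y in zip(lon.ravel(), lat.ravel())]
    ).reshape(lon.shape)
    return np.nonzero(inside)


def resample_polygon(
    areal: pd.Series | dict,
    polygon,
    population: np.ndarray,
    grid: GridSpec,
    rule: PointsPerCellRule = PointsPerCellRule(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Resample one areal observation to weighted pseudo-point clusters.

    Point locations are cell centres drawn (with replacement) with
    probability proportional to cell population; the number of points is
    proportional to the polygon's cell count; each point carries the full
    counts and weight 1/k, so weights sum to 1 and the weighted effective
    sample size equals the areal N.
    """
    rng = rng or np.random.default_rng()
    rows, cols = polygon_cells(polygon, grid)
    if len(rows) == 0:
        raise ValueError("polygon intersects no grid cell")
    pops = population[rows, cols]
    total = pops.sum()
    if total <= 0:
        raise ValueError("polygon has zero population")

    k = rule.n_points(len(rows))
    chosen = rng.choice(len(rows), size=k, p=pops / total)
    out = pd.DataFrame(
        {
            "cluster_id": [f"{areal['polygon_id']}_pt{i}" for i in range(k)],
            "lon": grid.lons[cols[chosen]],
            "lat": grid.lats[rows[chosen]],
            "year": int(areal["year"]),
            "weight": 1.0 / k,
            "N": int(areal["N"]),
            "anemic": int(areal["anemic"]),
            "mild": int(areal["mild"]),
            "moderate": int(areal["moderate"]),
            "severe": int(areal["severe"]),
        }
    )
    return out[CLUSTER_COLUMNS]
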