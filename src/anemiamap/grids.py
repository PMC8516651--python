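"""Regular lat/lon analysis grid shared by every raster in a scenario.

All rasters in a pipeline run are defined on a single :class:`GridSpec`
(cell-center convention), mirroring the approximately 5 x 5-km modelling
grids used in small-area prevalence mapping.  Rasters are stored as plain
``(n_rows, n_cols)`` float arrays; row 0 is the southernmost row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "write_raster", "read_raster"]

# Nominal km per degree at the equator; used only to scale the per-km2
# population masking threshold to the grid's cell size.
KM_PER_DEGREE = 111.32


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Cell-centre regular grid with an ordered list of annual time points.

    Parameters
    ----------
    origin_lon, origin_lat:
        Coordinates of the centre of cell ``(row=0, col=0)``, in degrees.
    cell_size:
        Cell edge length in degrees (> 0).
    n_rows, n_cols:
        Grid dimensions.
    years:
        Strictly increasing, consecutive calendar years.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    years: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")
        years = tuple(int(y) for y in self.years)
        if len(years) < 1 or any(b - a != 1 for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing and consecutive")
        object.__setattr__(self, "years", years)

    # -- geometry -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def lons(self) -> np.ndarray:
        """Cell-centre longitudes per column."""
        return self.origin_lon + self.cell_size * np.arange(self.n_cols)

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes per row (row 0 southernmost)."""
        return self.origin_lat + self.cell_size * np.arange(self.n_rows)

    @property
    def cell_area_km2(self) -> float:
        """Nominal cell area, ignoring latitude convergence (toy scale)."""
        return (self.cell_size * KM_PER_DEGREE) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of shape (n_rows, n_cols): lon and lat of every centre."""
        lon, lat = np.meshgrid(self.lons, self.lats)
        return lon, lat

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point; raises if outside."""
        col = np.rint((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        row = np.rint((np.asarray(lat) - self.origin_lat) / self.cell_size).astype(int)
        if np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise ValueError("point outside grid bounds")
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        half = self.cell_size / 2
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.origin_lon - half)
            & (lon <= self.origin_lon + self.cell_size * (self.n_cols - 1) + half)
            & (lat >= self.origin_lat - half)
            & (lat <= self.origin_lat + self.cell_size * (self.n_rows - 1) + half)
        )

    def year_index(self, year) -> np.ndarray:
        idx = np.asarray(year, dtype=int) - self.years[0]
        if np.any((idx < 0) | (idx >= self.n_years)):
            raise ValueError("year outside grid years")
        return idx

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "years": list(self.years),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            origin_lon=d["origin_lon"],
            origin_lat=d["origin_lat"],
            cell_size=d["cell_size"],
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            years=tuple(d["years"]),
        )


def write_raster(path: str | Path, array: np.ndarray, grid: GridSpec) -> None:
    """Write a raster as TIFF with a JSON sidecar holding the grid spec."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float64))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(grid.to_dict()))


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    import tifffile

    path = Path(path)
    array = np.asarray(tifffile.imread(path), dtype=np.float64)
    grid = GridSpec.from_dict(
        json.loads(path.with_suffix(path.suffix + ".json").read_text())
    )
    return array, grid
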