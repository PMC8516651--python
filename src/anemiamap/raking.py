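"""Raking: multiplicative calibration of grid draws to a national series.

The raking factor for a country-year is the ratio of the external national
estimate to the model's population-weighted national aggregate, computed per
posterior draw so that raked national aggregates match the series exactly in
every draw.  Factors are linearly interpolated between available years and
carried constant beyond the series (flagged extrapolated).  One overall-
anemia factor per country-year-draw multiplies all three severity marginals,
preserving the severity identity and within-country spatial variation; cells
raked above 1 are clipped with moderate re-derived as the residual.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = ["compute_raking_factors", "interpolate_factors", "apply_raking",
           "raking_table"]


def compute_raking_factors(
    national_draws: xr.DataArray,
    external: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-draw factors at the series years.

    Parameters
    ----------
    national_draws:
        Overall-anemia national aggregates, dims (draw, year, unit) with
        unit = country id.
    external:
        Columns country, year, value.

    Returns
    -------
    factors: (n_countries, D, n_avail) array; years: available years per
    country (n_countries, n_avail); countries: ids.
    """
    countries = [int(u) for u in national_draws["unit"].values]
    years_avail = sorted(external["year"].unique())
    D = national_draws.sizes["draw"]
    factors = np.empty((len(countries), D, len(years_avail)))
    series = external.set_index(["country", "year"])["value"]
    for ci, c in enumerate(countries):
        for yi, y in enumerate(years_avail):
            agg = national_draws.sel(unit=c, year=y).values  # (D,)
            if np.any(agg <= 0):
                raise ValueError(f"zero national aggregate for country {c}, year {y}")
            factors[ci, :, yi] = series[(c, y)] / agg
    return factors, np.array(years_avail), np.array(countries)


def interpolate_factors(
    factors: np.ndarray,
    avail_years: np.ndarray,
    target_years: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation to all target years, constant extrapolation.

    Returns (n_countries, D, n_target) factors and a provenance array of
    strings ``computed`` / ``interpolated`` / ``extrapolated`` per year.
    """
    avail_years = np.asarray(avail_years)
    target_years = np.asarray(target_years)
    if len(avail_years) < 1:
        raise ValueError("no available years to interpolate from")
    if len(avail_years) == 1:
        logger.warning("single raking year; factors held constant across years")
    nC, D, _ = factors.shape
    out = np.empty((nC, D, len(target_years)))
    for ci in range(nC):
        for d in range(D):
            out[ci, d] = np.interp(target_years, avail_years, factors[ci, d])
    provenance = np.where(
        np.isin(target_years, avail_years),
        "computed",
        np.where(
            (target_years > avail_years.max()) | (target_years < avail_years.min()),
            "extrapolated",
            "interpolated",
        ),
    ).astype(object)
    return out, provenance


def apply_raking(
    draws: xr.Dataset,
    factors: np.ndarray,
    countries: np.ndarray,
    country_map: np.ndarray,
) -> xr.Dataset:
    """Multiply each cell draw by its country-year factor.

    ``factors`` has shape (n_countries, D, n_years) aligned to the draws'
    year coordinate.  Severity marginals are scaled by the same factor;
    values clipped at 1 trigger a residual re-derivation of moderate so the
    identity mild + moderate + severe = overall is preserved exactly.
    """
    order = {int(c): i for i, c in enumerate(countries)}
    idx = np.vectorize(order.__getitem__)(country_map)  # (R, C) -> factor row
    D = draws.sizes["draw"]
    n_years = draws.sizes["year"]
    # per-cell factor field: (D, Y, R, C)
    f = factors[idx]  # (R, C, D, Y)
    f = np.moveaxis(f, (2, 3), (0, 1))

    overall = draws["overall"].values * f
    clipped = overall > 1.0
    if clipped.any():
        logger.warning("raking clipped %d cell-draws at 1.0", int(clipped.sum()))
        overall = np.minimum(overall, 1.0)

    out = {"overall": (("draw", "year", "row", "col"), overall)}
    if "mild" in draws:
        mild = np.minimum(draws["mild"].values * f, 1.0)
        severe = np.minimum(draws["severe"].values * f, 1.0)
        if clipped.any():
            # keep the identity where the overall hit the ceiling
            scale = np.where(clipped, overall / np.maximum(draws["overall"].values * f, 1e-12), 1.0)
            mild = mild * scale
            severe = severe * scale
        moderate = overall - mild - severe
        out.update(
            {
                "mild": (("draw", "year", "row", "col"), mild),
                "moderate": (("draw", "year", "row", "col"), np.maximum(moderate, 0.0)),
                "severe": (("draw", "year", "row", "col"), severe),
            }
        )
    return xr.Dataset(out, coords=draws.coords)


def raking_table(
    factors: np.ndarray,
    countries: np.ndarray,
    years: np.ndarray,
    provenance: np.ndarray,
    indicator: str = "overall",
) -> pd.DataFrame:
    """Tidy export: posterior-mean factor per country-year with provenance."""
    rows = []
    for ci, c in enumerate(countries):
        for yi, y in enumerate(years):
            rows.append(
                {
                    "country": int(c),
                    "year": int(y),
                    "indicator": indicator,
                    "factor": float(factors[ci, :, yi].mean()),
                    "provenance": str(provenance[yi]),
                }
            )
    return pd.DataFrame(rows)
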