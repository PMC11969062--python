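"""Climate handling: lapse-rate adjustment, range medians, subject-centering.

Site climate arrives as bioclim-style tables (mean annual temperature MAT,
annual precipitation AP, and temperature/precipitation of the coldest and
hottest quarters). Two preparation steps precede modelling:

1. Temperatures are lapse-rate adjusted (default 0.65 °C per 100 m) where the
   series' reported elevation deviates from the climate grid-cell elevation.
2. Subject-centering: each metric and non-climate numeric covariate is
   centered on its species mean, while climate variables are centered on the
   median climate of the species' range — so a centered climate value is the
   site's distance from the species' core climate (its marginality).

Numeric predictors are then scaled by their root mean square, pooled across
species, after centering. The response is centered but never scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mastgrad")

__all__ = [
    "CLIMATE_VARS",
    "TEMPERATURE_VARS",
    "RESPONSE_VARS",
    "CenteredDesign",
    "lapse_adjust",
    "adjust_site_temperatures",
    "range_medians",
    "center_design",
]

CLIMATE_VARS = ("mat", "ap", "t_hq", "p_hq", "t_cq", "p_cq")
TEMPERATURE_VARS = ("mat", "t_hq", "t_cq")
RESPONSE_VARS = ("cvp", "kcvp", "ar1", "psd")

#: Non-climate numeric covariates, centered on species means.
COVARIATE_VARS = ("n_years", "latitude")

DEFAULT_LAPSE = 0.65  # °C per 100 m


@dataclass
class CenteredDesign:
    """Centered, scaled design table plus the constants needed to invert it.

    ``table`` has one row per series: centered responses (suffix ``_c``),
    centered-and-scaled numeric predictors, and the categorical covariates.
    ``species_means``, ``range_medians`` and ``rms_scales`` record the
    centering constants and scales so predictions can be mapped back onto
    natural units.
    """

    table: pd.DataFrame
    species_means: pd.DataFrame
    range_medians: pd.DataFrame
    rms_scales: dict[str, float] = field(default_factory=dict)

    def sidecar(self) -> dict:
        """JSON-serialisable record of centering constants and scales."""
        return {
            "species_means": self.species_means.to_dict(orient="index"),
            "range_medians": self.range_medians.to_dict(orient="index"),
            "rms_scales": dict(self.rms_scales),
        }


def lapse_adjust(
    temp: float,
    series_elevation_m: float | None,
    grid_elevation_m: float | None,
    lapse: float = DEFAULT_LAPSE,
) -> float:
    """Adjust a temperature for the series/grid elevation difference.

    ``temp − lapse · (series_elevation − grid_elevation) / 100``: a series
    above its climate grid cell gets a cooler value. Precipitation is never
    adjusted. If either elevation is missing the temperature is returned
    unchanged (logged).
    """
    if (
        series_elevation_m is None
        or grid_elevation_m is None
        or (isinstance(series_elevation_m, float) and np.isnan(series_elevation_m))
        or (isinstance(grid_elevation_m, float) and np.isnan(grid_elevation_m))
    ):
        logger.debug("lapse_adjust: elevation missing, no adjustment")
        return float(temp)
    return float(temp - lapse * (series_elevation_m - grid_elevation_m) / 100.0)


def adjust_site_temperatures(
    climate: pd.DataFrame,
    series_elevation: pd.Series,
    lapse: float = DEFAULT_LAPSE,
) -> pd.DataFrame:
    """Lapse-adjust all temperature columns of a site-climate table.

    ``series_elevation`` is indexed by ``site_id``; sites without a reported
    elevation (or without grid elevation) are left unchanged.
    """
    out = climate.copy()
    elev = out["site_id"].map(series_elevation)
    grid = out.get("grid_elevation_m", pd.Series(np.nan, index=out.index))
    delta = (elev.to_numpy(dtype=float) - grid.to_numpy(dtype=float)) / 100.0
    delta = np.where(np.isnan(delta), 0.0, delta)
    for var in TEMPERATURE_VARS:
        out[var] = out[var] - lapse * delta
    return out


def range_medians(range_cells: pd.DataFrame, species_group: str | None = None) -> pd.DataFrame:
    """Per-species component-wise median climate over range cells.

    Each raster cell of the species range counts once (no area weighting);
    even cell counts use the midpoint convention of the ordinary median.
    Returns a table indexed by ``species_group``; restricting to one species
    errors if it has no cells.
    """
    if species_group is not None:
        cells = range_cells[range_cells["species_group"] == species_group]
        if cells.empty:
            raise ValueError(f"no range cells for species group {species_group!r}")
        range_cells = cells
    medians = range_cells.groupby("species_group")[list(CLIMATE_VARS)].median()
    return medians


def center_design(
    metrics: pd.DataFrame,
    climate: pd.DataFrame,
    ranges: pd.DataFrame,
    covariates: tuple[str, ...] = COVARIATE_VARS,
) -> CenteredDesign:
    """Build the subject-centered, RMS-scaled design table.

    Parameters
    ----------
    metrics
        Per-series metrics table (``metrics_table`` output): responses,
        ``n_years``, ``species_group``, ``site_id``, categoricals, latitude.
    climate
        Site climate, one row per ``site_id`` with the six bioclim variables.
    ranges
        Range-median climate per ``species_group`` (``range_medians`` output,
        or an equivalent table indexed by species_group).

    Responses are centered on species means (not scaled). Climate variables
    are centered on the species' range median, covariates on species means;
    all numeric predictors are then divided by their pooled root mean square
    sqrt(mean(x²)). Quadratic and interaction columns are *not* built here —
    the model module constructs them from the scaled linear columns.
    """
    if not isinstance(ranges.index, pd.Index) or ranges.index.name != "species_group":
        if "species_group" in ranges.columns:
            ranges = ranges.set_index("species_group")

    missing = set(metrics["species_group"]) - set(ranges.index)
    if missing:
        raise ValueError(f"species missing from range-climate table: {sorted(missing)}")

    table = metrics.merge(climate, on="site_id", how="left", validate="many_to_one")
    if table[list(CLIMATE_VARS)].isna().any().any():
        bad = table.loc[table[list(CLIMATE_VARS)].isna().any(axis=1), "site_id"].unique()
        raise ValueError(f"sites missing climate records: {sorted(map(str, bad))}")

    present_responses = [v for v in RESPONSE_VARS if v in table.columns]
    numeric_covs = [v for v in covariates if v in table.columns]

    species_means = table.groupby("species_group")[present_responses + numeric_covs].mean()

    out = table[["series_id", "species_group", "site_id"]].copy()
    for cat in ("variable_class", "collection_method"):
        if cat in table.columns:
            out[cat] = table[cat]

    for var in present_responses:
        out[f"{var}_c"] = table[var] - table["species_group"].map(species_means[var])

    rms_scales: dict[str, float] = {}

    def _scale(col: pd.Series, name: str) -> pd.Series:
        rms = float(np.sqrt(np.mean(np.square(col.to_numpy(dtype=float)))))
        if rms == 0:
            logger.warning("center_design: %s has zero RMS, left unscaled", name)
            rms = 1.0
        rms_scales[name] = rms
        return col / rms

    for var in numeric_covs:
        centered = table[var] - table["species_group"].map(species_means[var])
        out[var] = _scale(centered, var)

    for var in CLIMATE_VARS:
        centered = table[var] - table["species_group"].map(ranges[var])
        out[var] = _scale(centered, var)

    return CenteredDesign(
        table=out,
        species_means=species_means,
        range_medians=ranges[list(CLIMATE_VARS)].loc[sorted(set(table["species_group"]))],
        rms_scales=rms_scales,
    )
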