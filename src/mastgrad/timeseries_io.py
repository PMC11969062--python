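"""Reading, validating, grouping and filtering seed-crop time series.

Input is a long-format table of annual population-level reproduction records
(one row per series × year) in the style of the open MASTREE+ database:
series and site identifiers, species, year, crop value, what was measured
(cone/fruit/seed), how (seed trap / count / harvest), at what spatial scale,
with what unit class, plus coordinates and optional elevation.

The study filters keep quantitative stand- or patch-scale series with at
least ``min_years`` observed years, from species groups observed at at least
``min_sites`` distinct sites. The filter order is fixed: unit/scale
exclusions per series, then the length filter, then the site-count filter per
species group — so the site count reflects only analysable series.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mastgrad")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = [
    "SeedCropSeries",
    "REQUIRED_COLUMNS",
    "VARIABLE_CLASSES",
    "COLLECTION_METHODS",
    "SPATIAL_SCALES",
    "UNIT_CLASSES",
    "DEFAULT_SPECIES_GROUPING",
    "DEFAULT_METHOD_MAPPING",
    "read_series_table",
    "group_species",
    "group_methods",
    "apply_study_filters",
    "series_to_records",
    "write_series_tables",
]

REQUIRED_COLUMNS = (
    "series_id", "site_id", "species", "year", "value",
    "variable_class", "collection_method", "spatial_scale", "unit_class",
    "latitude", "longitude",
)

VARIABLE_CLASSES = frozenset({"cone", "fruit", "seed"})
COLLECTION_METHODS = frozenset({"seed_trap", "count", "harvest"})
SPATIAL_SCALES = frozenset({"stand", "patch", "regional", "super_regional"})
UNIT_CLASSES = frozenset({"quantitative", "ordinal", "index", "synchrony"})

ANALYSIS_SCALES = frozenset({"stand", "patch"})

#: Quercus robur and Q. petraea hybridize readily and mast in synchrony, so
#: their series are pooled into one analysis group.
DEFAULT_SPECIES_GROUPING = {
    "Quercus robur": "Quercus robur/petraea",
    "Quercus petraea": "Quercus robur/petraea",
}

#: Raw collection-method labels folded into the three analysis classes.
DEFAULT_METHOD_MAPPING = {
    "seed trap": "seed_trap",
    "litter trap": "seed_trap",
    "seed_trap": "seed_trap",
    "quadrat": "seed_trap",
    "count": "count",
    "visual cone count": "count",
    "visual count": "count",
    "cone count": "count",
    "harvest": "harvest",
    "harvest record": "harvest",
    "collection": "harvest",
}

_METADATA_COLUMNS = (
    "site_id", "species", "species_group", "variable_class",
    "collection_method", "spatial_scale", "unit_class",
    "latitude", "longitude", "elevation_m",
)


@dataclass
class SeedCropSeries:
    """One population's annual reproduction record.

    ``years`` and ``values`` are aligned arrays sorted by year with no
    duplicate years; ``metadata`` holds the per-series constant fields.
    """

    series_id: str
    species_group: str
    years: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ValueError(f"series {self.series_id}: years/values length mismatch")
        if len(np.unique(self.years)) != len(self.years):
            raise ValueError(f"series {self.series_id}: duplicate years")
        order = np.argsort(self.years)
        self.years = self.years[order]
        self.values = self.values[order]
        if np.any(self.values < 0):
            raise ValueError(f"series {self.series_id}: negative crop values")


def read_series_table(
    path,
    column_map: dict[str, str] | None = None,
    rejection_report: Path | None = None,
) -> pd.DataFrame:
    """Read a long-format seed-crop CSV into a validated record table.

    Parameters
    ----------
    path
        CSV with one row per (series, year). Column names may differ from the
        canonical ones; supply ``column_map`` mapping canonical → actual.
    column_map
        Optional renaming, e.g. ``{"value": "Count"}``.
    rejection_report
        Optional path; rejected rows are written there as CSV (row, reason).

    Rows with unparseable year/value or negative value are dropped with a
    logged warning; missing elevation is allowed. A missing mandatory column
    or an empty file is a hard error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty input file")
    if column_map:
        inverse = {actual: canonical for canonical, actual in column_map.items()}
        df = df.rename(columns=inverse)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if "elevation_m" not in df.columns:
        df["elevation_m"] = np.nan

    rejections = []
    year = pd.to_numeric(df["year"], errors="coerce")
    value = pd.to_numeric(df["value"], errors="coerce")
    bad_year = year.isna()
    bad_value = value.isna() | (value < 0)
    for idx in df.index[bad_year]:
        rejections.append({"row": int(idx), "reason": "unparseable year"})
    for idx in df.index[bad_value & ~bad_year]:
        rejections.append({"row": int(idx), "reason": "unparseable or negative value"})
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    bad_coord = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    for idx in df.index[bad_coord & ~bad_year & ~bad_value]:
        rejections.append({"row": int(idx), "reason": "invalid coordinates"})

    keep = ~(bad_year | bad_value | bad_coord)
    if rejections:
        logger.warning("%s: rejected %d of %d rows", path, len(rejections), len(df))
        if rejection_report is not None:
            pd.DataFrame(rejections).to_csv(rejection_report, index=False)
    out = df.loc[keep].copy()
    out["year"] = year[keep].astype(int)
    out["value"] = value[keep].astype(float)
    out["elevation_m"] = pd.to_numeric(out["elevation_m"], errors="coerce")

    dupes = out.duplicated(subset=["series_id", "year"])
    if dupes.any():
        dup_ids = sorted(out.loc[dupes, "series_id"].unique())
        raise ValueError(f"duplicate (series_id, year) rows in series: {dup_ids}")
    return out.reset_index(drop=True)


def group_species(records: pd.DataFrame, grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Assign ``species_group`` (default: pool Q. robur with Q. petraea).

    The original ``species`` column is retained.
    """
    if grouping is None:
        grouping = DEFAULT_SPECIES_GROUPING
    out = records.copy()
    out["species_group"] = out["species"].map(lambda s: grouping.get(s, s))
    return out


def group_methods(raw_method: str, mapping: dict[str, str] | None = None) -> str:
    """Map a raw collection-method label onto {seed_trap, count, harvest}."""
    if mapping is None:
        mapping = DEFAULT_METHOD_MAPPING
    key = raw_method.strip().lower()
    if key in COLLECTION_METHODS:
        return key
    if key not in mapping:
        raise ValueError(f"unmapped collection method label: {raw_method!r}")
    method = mapping[key]
    if method not in COLLECTION_METHODS:
        raise ValueError(
            f"mapping sends {raw_method!r} to {method!r}, not one of {sorted(COLLECTION_METHODS)}"
        )
    return method


def _records_to_series(records: pd.DataFrame) -> list[SeedCropSeries]:
    series = []
    for sid, grp in records.groupby("series_id", sort=True):
        meta = {}
        for col in _METADATA_COLUMNS:
            if col in grp.columns:
                vals = grp[col].dropna().unique()
                meta[col] = vals[0] if len(vals) else np.nan
        series.append(
            SeedCropSeries(
                series_id=str(sid),
                species_group=str(grp["species_group"].iloc[0]),
                years=grp["year"].to_numpy(),
                values=grp["value"].to_numpy(),
                metadata=meta,
            )
        )
    return series


def apply_study_filters(
    records: pd.DataFrame,
    min_years: int = 10,
    min_sites: int = 10,
) -> list[SeedCropSeries]:
    """Apply the study inclusion filters and return analysis-ready series.

    Order (fixed): quantitative-unit and stand/patch-scale exclusions per
    series → ``>= min_years`` observed years per series → ``>= min_sites``
    distinct sites per species group, counted over surviving series only.
    Both thresholds are inclusive. Returns an empty list (with a warning)
    when nothing survives.
    """
    if "species_group" not in records.columns:
        records = group_species(records)

    dupes = records.duplicated(subset=["series_id", "year"])
    if dupes.any():
        dup_ids = sorted(records.loc[dupes, "series_id"].unique())
        raise ValueError(f"duplicate (series_id, year) rows in series: {dup_ids}")

    mask = (
        records["unit_class"].eq("quantitative")
        & records["spatial_scale"].isin(ANALYSIS_SCALES)
    )
    kept = records.loc[mask]

    lengths = kept.groupby("series_id")["year"].nunique()
    long_enough = lengths.index[lengths >= min_years]
    kept = kept[kept["series_id"].isin(long_enough)]

    sites = kept.groupby("species_group")["site_id"].nunique()
    replicated = sites.index[sites >= min_sites]
    kept = kept[kept["species_group"].isin(replicated)]

    if kept.empty:
        logger.warning("apply_study_filters: no series survive the filters")
        return []
    return _records_to_series(kept)


def series_to_records(series_collection: list[SeedCropSeries]) -> pd.DataFrame:
    """Flatten series back to the long record format (inverse of filtering)."""
    frames = []
    for s in series_collection:
        df = pd.DataFrame({"series_id": s.series_id, "year": s.years, "value": s.values})
        for col in _METADATA_COLUMNS:
            if col in s.metadata:
                df[col] = s.metadata[col]
        df["species_group"] = s.species_group
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS) + ["species_group"])
    return pd.concat(frames, ignore_index=True)


def write_series_tables(series_collection, records_path, metadata_path) -> None:
    """Write the tidy per-year table and the per-series metadata table."""
    records = series_to_records(series_collection)
    records[["series_id", "year", "value"]].to_csv(records_path, index=False)
    meta_rows = []
    for s in series_collection:
        row = {"series_id": s.series_id, "species_group": s.species_group,
               "n_years": s.n_years}
        row.update(s.metadata)
        meta_rows.append(row)
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)
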