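"""Per-series masting statistics.

Four statistics summarise the temporal reproductive pattern of one
population-level seed-crop series:

* ``cvp`` — coefficient of variation of the annual crop (sd/mean, sample sd).
* ``kcvp`` — bounded transform of CVp, ``sqrt(CVp^2 / (1 + CVp^2))`` in [0, 1).
* ``ar1`` — lag-1 sample autocorrelation (divisor-n autocovariance convention,
  matching the default of R's ``Acf``/``acf``).
* ``psd`` — proportion of mast years, where a mast year is a year whose
  standardized deviate exceeds the absolute magnitude of the largest deviate
  below the mean (LaMontagne & Boutin rule), with a strict inequality.

Statistics that cannot be computed (constant series, zero mean, too few
years) are flagged missing with a reason rather than raising, so that a
metrics table over a heterogeneous corpus is always produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries_io import SeedCropSeries

__all__ = [
    "MastingMetrics",
    "cvp",
    "kcvp_from_cvp",
    "cvp_from_kcvp",
    "ar1",
    "mast_years",
    "psd",
    "compute_all",
    "metrics_table",
]


@dataclass
class MastingMetrics:
    """The four per-series statistics plus series length.

    Missing statistics are NaN with the reason recorded in
    ``missing_reasons[name]``.
    """

    series_id: str
    cvp: float
    kcvp: float
    ar1: float
    psd: float
    n_years: int
    missing_reasons: dict[str, str] = field(default_factory=dict)


def _as_array(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    return x


def cvp(values) -> float:
    """Coefficient of variation: sample sd (n−1 denominator) over the mean.

    Raises ``ValueError`` for series shorter than 2 or with zero mean;
    ``compute_all`` converts these into missing flags.
    """
    x = _as_array(values)
    if x.size < 2:
        raise ValueError("series too short for cvp (need >= 2 years)")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero-mean series")
    return float(x.std(ddof=1) / mean)


def kcvp_from_cvp(cv: float) -> float:
    """Bounded masting-variability index: sqrt(CVp² / (1 + CVp²)) ∈ [0, 1)."""
    if cv < 0:
        raise ValueError("cvp must be non-negative")
    return float(np.sqrt(cv * cv / (1.0 + cv * cv)))


def cvp_from_kcvp(k: float) -> float:
    """Inverse of :func:`kcvp_from_cvp`: CVp = kCVp / sqrt(1 − kCVp²)."""
    if not 0 <= k < 1:
        raise ValueError("kcvp must be in [0, 1)")
    return float(k / np.sqrt(1.0 - k * k))


def ar1(values) -> float:
    """Lag-1 sample autocorrelation.

    Uses the standard autocovariance convention (the one behind R's
    ``Acf``): demean by the series mean and divide the lag-1 autocovariance
    by the lag-0 autocovariance, both with divisor n (which cancels):

        r1 = sum_{t=1}^{n-1} (x_t − x̄)(x_{t+1} − x̄) / sum_{t=1}^{n} (x_t − x̄)²

    This differs from the (n−1)-pairs convention at small n.
    """
    x = _as_array(values)
    if x.size < 2:
        raise ValueError("series too short for ar1 (need >= 2 years)")
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("zero-variance series")
    return float(d[:-1] @ d[1:] / denom)


def mast_years(values) -> np.ndarray:
    """Boolean mast-year indicator by the standardized-deviate rule.

    Deviates d_t = (x_t − x̄)/s with the sample sd; the threshold is the
    absolute magnitude of the largest deviate below the mean, T = |min d_t|;
    year t is a mast year iff d_t > T (strict — a tie at exactly T is not a
    mast year). A zero-variance series has no mast years.
    """
    x = _as_array(values)
    if x.size < 3:
        raise ValueError("series too short for mast-year detection (need >= 3 years)")
    s = x.std(ddof=1)
    if s == 0:
        return np.zeros(x.size, dtype=bool)
    d = (x - x.mean()) / s
    threshold = abs(d.min())
    return d > threshold


def psd(values) -> float:
    """Proportion of mast years: count(mast_years) / n_years."""
    flags = mast_years(values)
    return float(flags.sum() / flags.size)


def compute_all(series: SeedCropSeries) -> MastingMetrics:
    """Bundle the four statistics for one series, flagging what is missing."""
    x = np.asarray(series.values, dtype=float)
    reasons: dict[str, str] = {}

    if np.any(np.diff(np.asarray(series.years)) > 1):
        warnings.warn(
            f"series {series.series_id}: gap years present; ar1 treats observed "
            "years as consecutive",
            stacklevel=2,
        )

    try:
        cv = cvp(x)
        kcv = kcvp_from_cvp(cv)
    except ValueError as exc:
        cv = kcv = float("nan")
        reasons["cvp"] = reasons["kcvp"] = str(exc)

    try:
        r1 = ar1(x)
    except ValueError as exc:
        r1 = float("nan")
        reasons["ar1"] = str(exc)

    try:
        p = psd(x)
    except ValueError as exc:
        p = float("nan")
        reasons["psd"] = str(exc)

    return MastingMetrics(
        series_id=series.series_id,
        cvp=cv,
        kcvp=kcv,
        ar1=r1,
        psd=p,
        n_years=series.n_years,
        missing_reasons=reasons,
    )


def metrics_table(series_collection: list[SeedCropSeries]) -> pd.DataFrame:
    """Metrics for a series collection as a tidy table.

    One row per series: the four statistics, ``n_years``, per-series constant
    metadata needed downstream (species group, site, method, variable class,
    latitude), and a ``missing`` column with semicolon-joined reasons.
    """
    rows = []
    for s in series_collection:
        m = compute_all(s)
        row = {
            "series_id": m.series_id,
            "cvp": m.cvp,
            "kcvp": m.kcvp,
            "ar1": m.ar1,
            "psd": m.psd,
            "n_years": m.n_years,
            "missing": ";".join(f"{k}: {v}" for k, v in sorted(m.missing_reasons.items())),
        }
        for key in ("species_group", "site_id", "collection_method", "variable_class",
                    "latitude", "longitude", "elevation_m"):
            if key in s.metadata:
                row[key] = s.metadata[key]
        rows.append(row)
    return pd.DataFrame(rows)
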