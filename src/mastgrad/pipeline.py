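"""End-to-end convenience wrappers: study bundle → metrics → design → fits.

These are thin compositions of the library modules, shared by the analysis
drivers, the test suite and the acceptance script so that "the pipeline" is
one code path everywhere.
"""

from __future__ import annotations

import pandas as pd

from . import climate as climate_mod
from . import marginality_model as mm
from .metrics import metrics_table
from .synthetic_data import StudyBundle
from .timeseries_io import apply_study_filters, group_species

__all__ = ["prepare_design", "fit_study_model", "lrt_table", "wald_table"]


def prepare_design(
    series: pd.DataFrame,
    site_climate: pd.DataFrame,
    range_cells: pd.DataFrame,
    min_years: int = 10,
    min_sites: int = 10,
) -> climate_mod.CenteredDesign:
    """Records + climate tables → filtered metrics → centered design table."""
    records = group_species(series)
    kept = apply_study_filters(records, min_years=min_years, min_sites=min_sites)
    metrics = metrics_table(kept)
    ranges = climate_mod.range_medians(range_cells)
    return climate_mod.center_design(metrics, site_climate, ranges)


def fit_study_model(
    bundle: StudyBundle,
    response: str,
    flavor: str = "annual",
    **fit_kw,
) -> tuple[mm.FitResult, climate_mod.CenteredDesign]:
    """Fit one subject-centered model on a simulated study bundle."""
    centered = prepare_design(bundle.series, bundle.climate, bundle.range_cells)
    spec = mm.ModelSpec(response=response, flavor=flavor)
    fit = mm.fit_model(spec, centered, **fit_kw)
    return fit, centered


def wald_table(fit: mm.FitResult) -> pd.DataFrame:
    """Coefficient table (term, estimate, SE, z, p) for reporting."""
    out = fit.coefficients.copy()
    out.index.name = "term"
    return out.reset_index()


def lrt_table(
    spec: mm.ModelSpec,
    centered: climate_mod.CenteredDesign | pd.DataFrame,
    **fit_kw,
) -> pd.DataFrame:
    """Likelihood-ratio tests for every linear climate term of the model."""
    rows = []
    for focal in spec.linear_climate_terms:
        res = mm.lrt_linear_term(spec, centered, focal, **fit_kw)
        rows.append({
            "term": focal, "statistic": res.statistic, "df": res.df,
            "p": res.p, "full_loglik": res.full_loglik,
            "reduced_loglik": res.reduced_loglik, "valid": res.valid,
        })
    return pd.DataFrame(rows)
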