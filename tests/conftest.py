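import numpy as np
import pandas as pd
import pytest

from mastgrad.synthetic_data import SimulationConfig, simulate_study


def make_records(
    n_series=12,
    n_sites=12,
    n_years=12,
    species="Fagus sylvatica",
    spatial_scale="stand",
    unit_class="quantitative",
    seed=0,
):
    """Small hand-controllable long-format record table."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_series):
        site = f"site{i % n_sites:02d}"
        for t in range(n_years):
            rows.append({
                "series_id": f"ser{i:02d}",
                "site_id": site,
                "species": species,
                "year": 1990 + t,
                "value": float(rng.lognormal(0.0, 0.5)),
                "variable_class": "seed",
                "collection_method": "seed_trap",
                "spatial_scale": spatial_scale,
                "unit_class": unit_class,
                "latitude": 50.0 + i * 0.1,
                "longitude": 10.0,
                "elevation_m": 300.0,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_study():
    """A compact but fully structured study bundle (6 species x 15 sites)."""
    cfg = SimulationConfig(n_species=6, sites_per_species=15, n_range_cells=80, seed=42)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The default-conditions study bundle (19 species x 23 sites)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def species_rich_study():
    """Few species, many sites each — the species-specific modelling regime."""
    cfg = SimulationConfig(n_species=4, sites_per_species=45, n_range_cells=80, seed=21)
    return simulate_study(cfg)
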