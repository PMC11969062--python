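"""Synthetic masting studies with known climate-effect surfaces.

Generates complete fake studies — species range-climate cells, site climate
records, and annual seed-crop series — so every pipeline stage (filtering,
metrics, centering, model fitting, surfaces) can be exercised and validated
against known truth without any external downloads.

Study structure mirrors a MASTREE+-scale corpus: 19 species × 23 sites ≈ 437
series of 10–62 years (mean ≈ 18.5). Each species has a climate centroid;
range cells and sites are drawn uniformly around it, so a site's centered
climate (site − range median) spans the configured gradient.

The seed-crop process for one series combines
  * a latent AR(1) log-baseline  b_t = μ + φ(b_{t−1} − μ) + ε_t,  ε ~ N(0, τ²)
  * episodic mast events  m_t ~ Bernoulli(p_m), crop x_t = exp(b_t)(1 + (M−1) m_t)

Site-level mast probability p_m and multiplier M are deterministic functions
of centered climate through the configured true effects (inverse-logit link
for p_m, log link for M). A negative MAT² effect on p_m makes mast years
rarest at the climatic margins; a negative MAT effect on M lowers crop
variability toward the warm margin. The three dials are deliberately
separable: M and τ move CVp, φ and mast spacing move AR(1), p_m moves Psd.

A second generator (``simulate_metric_table``) draws metric-level responses
directly from the heteroscedastic Gaussian model on a study-like design, for
parameter-recovery and calibration experiments where an exact coefficient
truth is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "simulate_ranges_and_sites",
    "site_mast_params",
    "simulate_series",
    "simulate_study",
    "simulate_metric_table",
]

DEFAULT_SEED = 20250403

_SPECIES_POOL = [
    "Picea abies", "Picea glauca", "Picea engelmannii", "Pinus sylvestris",
    "Pinus edulis", "Pinus ponderosa", "Fagus sylvatica", "Fagus crenata",
    "Quercus robur/petraea", "Quercus douglasii", "Quercus crispula",
    "Abies amabilis", "Abies alba", "Alnus incana", "Betula pendula",
    "Nothofagus solandri", "Araucaria araucana", "Tsuga heterophylla",
    "Larix decidua", "Pseudotsuga menziesii", "Sorbus aucuparia",
]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    ``climate_gradients`` maps a base climate variable to (median, span):
    species centroids sit at the median (jittered between species) and range
    cells/sites are drawn uniformly within ±span of the centroid. True
    effects are expressed per response on the generator's standardized
    climate scale z = (site − range median)/span: ``psd`` effects shift the
    mast-probability logit, ``cvp`` effects shift log mast-multiplier.
    """

    n_species: int = 19
    sites_per_species: int = 23
    years_range: tuple[int, int] = (10, 62)
    mean_years: float = 18.5
    n_range_cells: int = 200
    climate_gradients: dict = field(default_factory=lambda: {
        "mat": (8.0, 4.0),      # °C
        "ap": (900.0, 350.0),   # mm/yr
    })
    true_effects: dict = field(default_factory=lambda: {
        "psd": {"mat^2": -1.0},   # logit p_m per z²: mast years rarer at margins
        "cvp": {"mat": -0.35},    # log M per z: smaller mast events at warm margin
    })
    series_process: dict = field(default_factory=lambda: {
        "log_baseline_mean": 0.0,
        "log_noise_sd": 0.5,
        "ar_coefficient": 0.2,
        "mast_probability": 0.2,
        "mast_multiplier": 6.0,
    })
    method_mix: dict = field(default_factory=lambda: {
        "seed_trap": 0.5, "count": 0.3, "harvest": 0.2,
    })
    variable_mix: dict = field(default_factory=lambda: {
        "seed": 0.6, "cone": 0.25, "fruit": 0.15,
    })
    dispersion_truth: dict = field(default_factory=dict)  # species → log-sd offset
    grid_elevation_jitter_sd: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        proc = self.series_process
        if not -1 < proc["ar_coefficient"] < 1:
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if not 0 < proc["mast_probability"] < 1:
            raise ValueError("mast_probability must lie in (0, 1)")
        if proc["mast_multiplier"] <= 1:
            raise ValueError("mast_multiplier must exceed 1")
        lo, hi = self.years_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid years_range")


@dataclass
class StudyBundle:
    """One simulated study: inputs for the pipeline plus the ground truth."""

    series: pd.DataFrame       # long SeedCropRecord table
    climate: pd.DataFrame      # per-site ClimateRecord table
    range_cells: pd.DataFrame  # per-species range-climate cells
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(out / "series.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        self.range_cells.to_csv(out / "range_cells.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def _derive_quarters(rng, mat, ap):
    """Quarter climate from annual values; t_cq <= mat <= t_hq by construction."""
    n = len(mat)
    t_hq = mat + rng.uniform(8.0, 12.0, n)
    t_cq = mat - rng.uniform(8.0, 12.0, n)
    p_hq = ap * rng.uniform(0.2, 0.4, n)
    p_cq = ap * rng.uniform(0.1, 0.3, n)
    return t_hq, t_cq, p_hq, p_cq


def simulate_ranges_and_sites(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Draw per-species range cells and site climates from one distribution.

    Returns ``(range_cells, sites)``. ``sites`` carries the true standardized
    centered climate (``mat_z``, ``ap_z``) used by the series generator, plus
    site metadata (species, coordinates, elevation).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    species = _SPECIES_POOL[: config.n_species]
    if config.n_species > len(_SPECIES_POOL):
        species = species + [f"Species {i}" for i in range(len(_SPECIES_POOL), config.n_species)]

    (mat_med, mat_span) = config.climate_gradients["mat"]
    (ap_med, ap_span) = config.climate_gradients["ap"]

    cell_rows, site_rows = [], []
    for s_idx, sp in enumerate(species):
        centroid_mat = mat_med + rng.uniform(-3.0, 3.0)
        centroid_ap = ap_med + rng.uniform(-150.0, 150.0)
        lat_band = rng.uniform(42.0, 58.0)

        n_cells = config.n_range_cells
        c_mat = centroid_mat + rng.uniform(-mat_span, mat_span, n_cells)
        c_ap = np.maximum(centroid_ap + rng.uniform(-ap_span, ap_span, n_cells), 50.0)
        t_hq, t_cq, p_hq, p_cq = _derive_quarters(rng, c_mat, c_ap)
        for j in range(n_cells):
            cell_rows.append({
                "species_group": sp, "cell_id": f"{s_idx:02d}c{j:03d}",
                "mat": c_mat[j], "ap": c_ap[j], "t_hq": t_hq[j], "p_hq": p_hq[j],
                "t_cq": t_cq[j], "p_cq": p_cq[j],
            })

        n_sites = config.sites_per_species
        z_mat = rng.uniform(-1.0, 1.0, n_sites)
        z_ap = rng.uniform(-1.0, 1.0, n_sites)
        s_mat = centroid_mat + z_mat * mat_span
        s_ap = np.maximum(centroid_ap + z_ap * ap_span, 50.0)
        t_hq, t_cq, p_hq, p_cq = _derive_quarters(rng, s_mat, s_ap)
        elevation = rng.uniform(0.0, 1500.0, n_sites)
        grid_elev = elevation + rng.normal(0.0, config.grid_elevation_jitter_sd, n_sites)
        for j in range(n_sites):
            site_rows.append({
                "site_id": f"{s_idx:02d}s{j:02d}", "species_group": sp,
                "mat": s_mat[j], "ap": s_ap[j], "t_hq": t_hq[j], "p_hq": p_hq[j],
                "t_cq": t_cq[j], "p_cq": p_cq[j],
                "grid_elevation_m": grid_elev[j], "elevation_m": elevation[j],
                "latitude": lat_band + rng.uniform(-3.0, 3.0),
                "longitude": rng.uniform(-120.0, 30.0),
                "mat_z": z_mat[j], "ap_z": z_ap[j],
                "centroid_mat": centroid_mat, "centroid_ap": centroid_ap,
            })
    return pd.DataFrame(cell_rows), pd.DataFrame(site_rows)


def _effect_shift(effects: dict[str, float], z: dict[str, float]) -> float:
    shift = 0.0
    for term, coef in effects.items():
        if term.endswith("^2"):
            shift += coef * z[term[:-2]] ** 2
        elif ":" in term:
            a, b = term.split(":")
            shift += coef * z[a] * z[b]
        else:
            shift += coef * z[term]
    return shift


def site_mast_params(config: SimulationConfig, z: dict[str, float]) -> tuple[float, float]:
    """Deterministic site-level (mast probability, mast multiplier).

    ``z`` holds the site's standardized centered climate. The configured
    ``psd`` effects move the mast-probability logit; the ``cvp`` effects move
    the log mast-multiplier.
    """
    proc = config.series_process
    p0, m0 = proc["mast_probability"], proc["mast_multiplier"]
    logit_p = np.log(p0 / (1 - p0)) + _effect_shift(config.true_effects.get("psd", {}), z)
    p_m = 1.0 / (1.0 + np.exp(-logit_p))
    log_m = np.log(m0) + _effect_shift(config.true_effects.get("cvp", {}), z)
    mult = float(np.exp(log_m))
    return float(p_m), max(mult, 1.0 + 1e-9)


def simulate_series(
    p_m: float,
    mast_multiplier: float,
    n_years: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    log_sd_offset: float = 0.0,
) -> np.ndarray:
    """One seed-crop series: AR(1) lognormal baseline + multiplicative masts."""
    proc = config.series_process
    mu = proc["log_baseline_mean"]
    tau = proc["log_noise_sd"] * float(np.exp(log_sd_offset))
    phi = proc["ar_coefficient"]

    b = np.empty(n_years)
    stat_sd = tau / np.sqrt(1.0 - phi**2) if tau > 0 else 0.0
    b[0] = mu + rng.normal(0.0, stat_sd) if stat_sd > 0 else mu
    innov = rng.normal(0.0, tau, n_years - 1) if tau > 0 else np.zeros(n_years - 1)
    for t in range(1, n_years):
        b[t] = mu + phi * (b[t - 1] - mu) + innov[t - 1]
    mast = rng.uniform(size=n_years) < p_m
    return np.exp(b) * (1.0 + (mast_multiplier - 1.0) * mast)


def _draw_n_years(config: SimulationConfig, rng) -> int:
    lo, hi = config.years_range
    extra_mean = max(config.mean_years - lo, 0.5)
    n = lo + rng.geometric(1.0 / (extra_mean + 1.0)) - 1
    return int(min(n, hi))


def simulate_study(config: SimulationConfig | None = None, out_dir=None) -> StudyBundle:
    """Generate a full study: series, site climate, range cells, truth file.

    One series per site. The output passes the study filters unchanged
    (stand scale, quantitative units, >=10 years, >=10 sites per species).
    Deterministic in ``config.seed``: reruns produce byte-identical CSVs.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    range_cells, sites = simulate_ranges_and_sites(config, rng)

    methods = list(config.method_mix)
    method_p = np.array([config.method_mix[m] for m in methods], float)
    method_p /= method_p.sum()
    variables = list(config.variable_mix)
    variable_p = np.array([config.variable_mix[v] for v in variables], float)
    variable_p /= variable_p.sum()

    rows = []
    truth_sites = {}
    for _, site in sites.iterrows():
        z = {"mat": site["mat_z"], "ap": site["ap_z"]}
        p_m, mult = site_mast_params(config, z)
        n_years = _draw_n_years(config, rng)
        offset = config.dispersion_truth.get(site["species_group"], 0.0)
        values = simulate_series(p_m, mult, n_years, config, rng, log_sd_offset=offset)
        start = int(rng.integers(1950, 2000))
        method = methods[rng.choice(len(methods), p=method_p)]
        variable = variables[rng.choice(len(variables), p=variable_p)]
        sid = f"S_{site['site_id']}"
        truth_sites[sid] = {"p_m": p_m, "mast_multiplier": mult,
                            "mat_z": float(z["mat"]), "ap_z": float(z["ap"])}
        for t in range(n_years):
            rows.append({
                "series_id": sid, "site_id": site["site_id"],
                "species": site["species_group"], "year": start + t,
                "value": values[t], "variable_class": variable,
                "collection_method": method, "spatial_scale": "stand",
                "unit_class": "quantitative",
                "latitude": site["latitude"], "longitude": site["longitude"],
                "elevation_m": site["elevation_m"],
            })

    series = pd.DataFrame(rows)
    climate_cols = ["site_id", "mat", "ap", "t_hq", "p_hq", "t_cq", "p_cq",
                    "grid_elevation_m"]
    truth = {
        "seed": config.seed,
        "true_effects": config.true_effects,
        "series_process": config.series_process,
        "climate_gradients": {k: list(v) for k, v in config.climate_gradients.items()},
        "species_centroids": {
            sp: {"mat": float(g["centroid_mat"].iloc[0]), "ap": float(g["centroid_ap"].iloc[0])}
            for sp, g in sites.groupby("species_group")
        },
        "sites": truth_sites,
    }
    bundle = StudyBundle(
        series=series,
        climate=sites[climate_cols].copy(),
        range_cells=range_cells,
        truth=truth,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def simulate_metric_table(
    config: SimulationConfig,
    beta: dict[str, float],
    sigma0: float,
    response: str = "psd",
    dispersion: dict[str, dict[str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Metric-level responses drawn directly from the regression model.

    Builds a study-like centered/scaled design (uniform climate columns with
    the study's species/method/variable structure) and draws

        y_i = x_i' beta + eps_i,   eps_i ~ N(0, sigma_i²),
        log sigma_i = log sigma0 + sum of configured group offsets,

    where ``beta`` maps annual-model term names (``mat``, ``mat^2``,
    ``mat:ap``, …) to true coefficients. Because the fitted model is exactly
    the generating model, coefficient recovery and Wald coverage have exact
    truth. Returns a table ready for ``build_design`` with response column
    ``<response>_c``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_species * config.sites_per_species
    species = [
        _SPECIES_POOL[i % len(_SPECIES_POOL)]
        for i in range(config.n_species) for _ in range(config.sites_per_species)
    ]
    methods = list(config.method_mix)
    method_p = np.array([config.method_mix[m] for m in methods], float)
    method_p /= method_p.sum()
    variables = list(config.variable_mix)
    variable_p = np.array([config.variable_mix[v] for v in variables], float)
    variable_p /= variable_p.sum()

    table = pd.DataFrame({
        "series_id": [f"R{i:04d}" for i in range(n)],
        "species_group": species,
        "mat": rng.uniform(-1.0, 1.0, n),
        "ap": rng.uniform(-1.0, 1.0, n),
        "n_years": rng.normal(0.0, 1.0, n),
        "latitude": rng.normal(0.0, 1.0, n),
        "variable_class": rng.choice(variables, size=n, p=variable_p),
        "collection_method": rng.choice(methods, size=n, p=method_p),
    })

    eta = np.zeros(n)
    for term, coef in beta.items():
        if term == "(Intercept)":
            eta += coef
        elif "[" in term:  # categorical effect, e.g. "collection_method[count]"
            factor, level = term[:-1].split("[")
            eta += coef * (table[factor] == level).to_numpy(float)
        elif term.endswith("^2"):
            eta += coef * table[term[:-2]].to_numpy() ** 2
        elif ":" in term:
            a, b = term.split(":")
            eta += coef * table[a].to_numpy() * table[b].to_numpy()
        else:
            eta += coef * table[term].to_numpy()

    log_sd = np.full(n, np.log(sigma0))
    for factor, offsets in (dispersion or {}).items():
        for level, off in offsets.items():
            log_sd += off * (table[factor] == level).to_numpy(float)

    table[f"{response}_c"] = eta + np.exp(log_sd) * rng.standard_normal(n)
    return table
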