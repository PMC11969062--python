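"""Heteroscedastic Gaussian fits, Wald/LRT inference and GVIF screening."""

import numpy as np
import pandas as pd
import pytest

from mastgrad import marginality_model as mm
from mastgrad.synthetic_data import SimulationConfig, simulate_metric_table


def _random_fixture(rng, n=60, p=3, het=False):
    X = pd.DataFrame(
        np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]),
        columns=["(Intercept)"] + [f"x{i}" for i in range(1, p)],
    )
    if het:
        g = rng.integers(0, 2, n).astype(float)
        Z = pd.DataFrame({"(Intercept)": np.ones(n), "g[b]": g})
    else:
        Z = pd.DataFrame({"(Intercept)": np.ones(n)})
    beta = rng.normal(size=p)
    sd = np.exp(Z.to_numpy() @ rng.normal(scale=0.3, size=Z.shape[1]))
    y = X.to_numpy() @ beta + sd * rng.standard_normal(n)
    return X, Z, y


class TestHomoscedasticLimit:
    def test_matches_ols_ml_oracle(self):
        """With intercept-only dispersion the MLE equals OLS + divisor-n variance."""
        import statsmodels.api as sm

        rng = np.random.default_rng(20240601)
        for _ in range(50):
            X, Z, y = _random_fixture(rng, n=int(rng.integers(20, 80)))
            fit = mm.fit_hetero_gaussian(X, Z, y)
            ols = sm.OLS(y, X.to_numpy()).fit()
            assert fit.converged
            assert np.max(np.abs(fit.beta - ols.params)) < 1e-6
            s2 = np.mean((y - X.to_numpy() @ ols.params) ** 2)
            ll = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)
            assert fit.loglik == pytest.approx(ll, abs=1e-6)
            assert np.exp(fit.gamma[0]) == pytest.approx(np.sqrt(s2), rel=1e-6)

    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"(Intercept)": [1.0, 1.0, 1.0]})
        Z = X.copy()
        fit = mm.fit_hetero_gaussian(X, Z, np.array([1.0, 2.0, 3.0]))
        assert fit.beta[0] == pytest.approx(2.0, abs=1e-8)
        assert np.exp(fit.gamma[0]) == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-8)


class TestDispersionModel:
    def test_doubled_sd_recovered(self):
        """Group with doubled residual sd: exp(gamma) within 2 SE of 2."""
        rng = np.random.default_rng(99)
        n = 2000
        g = rng.integers(0, 2, n).astype(float)
        X = pd.DataFrame({"(Intercept)": np.ones(n), "x": rng.normal(size=n)})
        Z = pd.DataFrame({"(Intercept)": np.ones(n), "grp[b]": g})
        y = 0.2 + 0.5 * X["x"].to_numpy() + 0.4 * np.exp(np.log(2.0) * g) * rng.standard_normal(n)
        fit = mm.fit_hetero_gaussian(X, Z, y)
        est, se = fit.dispersion.loc["grp[b]", ["estimate", "se"]]
        assert np.exp(est - 2 * se) <= 2.0 <= np.exp(est + 2 * se)

    def test_likelihood_never_decreases_with_extra_term(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            X, Z, y = _random_fixture(rng, n=50, het=True)
            small = mm.fit_hetero_gaussian(X, Z[["(Intercept)"]], y)
            big = mm.fit_hetero_gaussian(X, Z, y)
            assert big.loglik >= small.loglik - 1e-6


class TestInvariance:
    def test_predictor_rescaling(self):
        """x -> c·x multiplies beta by 1/c; loglik, z unchanged."""
        rng = np.random.default_rng(11)
        X, Z, y = _random_fixture(rng, n=120, het=True)
        f1 = mm.fit_hetero_gaussian(X, Z, y)
        X2 = X.copy()
        X2["x1"] = X2["x1"] * 3.7
        f2 = mm.fit_hetero_gaussian(X2, Z, y)
        assert f2.coefficients.loc["x1", "estimate"] == pytest.approx(
            f1.coefficients.loc["x1", "estimate"] / 3.7, rel=1e-6)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)
        assert f2.coefficients.loc["x1", "z"] == pytest.approx(
            f1.coefficients.loc["x1", "z"], rel=1e-5)


class TestBuildDesign:
    def test_annual_and_seasonal_term_sets(self, small_study):
        from mastgrad.pipeline import prepare_design

        cd = prepare_design(small_study.series, small_study.climate,
                            small_study.range_cells)
        d_ann = mm.build_design(mm.ModelSpec(response="cvp"), cd.table)
        for t in ("mat", "ap", "mat:ap", "mat^2", "ap^2", "n_years"):
            assert t in d_ann.X.columns
        assert "latitude" not in d_ann.X.columns

        d_sea = mm.build_design(mm.ModelSpec(response="cvp", flavor="seasonal"), cd.table)
        climate_cols = [c for c in d_sea.X.columns
                        if any(v in c for v in ("t_hq", "p_hq", "t_cq", "p_cq"))]
        assert len(climate_cols) == 10

        d_ar = mm.build_design(mm.ModelSpec(response="ar1"), cd.table)
        assert "latitude" in d_ar.X.columns

    def test_single_level_categorical_dropped(self):
        tbl = pd.DataFrame({
            "cvp_c": np.random.default_rng(0).normal(size=30),
            "mat": np.random.default_rng(1).normal(size=30),
            "ap": np.random.default_rng(2).normal(size=30),
            "n_years": 0.0,
            "variable_class": "seed",
            "collection_method": "seed_trap",
            "species_group": "A",
        })
        tbl["n_years"] = np.random.default_rng(3).normal(size=30)
        d = mm.build_design(mm.ModelSpec(response="cvp"), tbl)
        assert "variable_class" in d.dropped_terms
        assert not any(c.startswith("variable_class[") for c in d.X.columns)

    def test_rank_deficient_design_names_aliased_column(self):
        rng = np.random.default_rng(4)
        tbl = pd.DataFrame({
            "cvp_c": rng.normal(size=40),
            "mat": rng.normal(size=40),
            "ap": rng.normal(size=40),
            "n_years": 0.0,
            "species_group": "A",
        })
        tbl["n_years"] = tbl["mat"]  # exact alias
        with pytest.raises(ValueError, match="rank-deficient"):
            mm.build_design(
                mm.ModelSpec(response="cvp",
                             mean_terms=("mat", "ap", "n_years")), tbl)

    def test_treatment_coding_reference_is_alphabetical(self, small_study):
        from mastgrad.pipeline import prepare_design

        cd = prepare_design(small_study.series, small_study.climate,
                            small_study.range_cells)
        d = mm.build_design(mm.ModelSpec(response="cvp"), cd.table)
        levels = sorted(cd.table["collection_method"].unique())
        assert f"collection_method[{levels[0]}]" not in d.X.columns
        for lev in levels[1:]:
            assert f"collection_method[{lev}]" in d.X.columns


class TestLRT:
    def test_statistic_nonnegative_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        cfg = SimulationConfig(n_species=5, sites_per_species=12, seed=1)
        spec = mm.ModelSpec(response="psd")
        for i in range(25):
            tbl = simulate_metric_table(
                cfg, beta={"ap": 0.01 * rng.normal()}, sigma0=0.05,
                rng=np.random.default_rng(1000 + i))
            res = mm.lrt_linear_term(spec, tbl, "mat")
            assert res.statistic >= 0.0
            assert 0.0 <= res.p <= 1.0

    def test_strong_effect_detected(self):
        cfg = SimulationConfig(n_species=8, sites_per_species=20, seed=2)
        tbl = simulate_metric_table(cfg, beta={"mat": 0.05}, sigma0=0.04,
                                    rng=np.random.default_rng(5))
        res = mm.lrt_linear_term(mm.ModelSpec(response="psd"), tbl, "mat")
        assert res.p < 1e-4

    def test_focal_must_be_linear_climate_term(self, small_study):
        spec = mm.ModelSpec(response="psd")
        with pytest.raises(ValueError):
            mm.lrt_linear_term(spec, pd.DataFrame(), "n_years")

    def test_full_model_strips_focal_quadratic_and_interaction(self):
        spec = mm.ModelSpec(response="psd")
        full = mm._strip_focal(spec.mean_terms, "mat", drop_linear=False)
        assert "mat" in full and "mat^2" not in full and "mat:ap" not in full
        assert "ap^2" in full
        reduced = mm._strip_focal(spec.mean_terms, "mat", drop_linear=True)
        assert "mat" not in reduced


class TestGVIF:
    def test_orthogonal_predictors_unity(self):
        n = 128
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"(Intercept)": 1.0, "x1": x1, "x2": x2})
        vifs = mm.gvif(X, {"x1": ["x1"], "x2": ["x2"]})
        assert vifs["x1"] == pytest.approx(1.0, abs=1e-9)
        assert vifs["x2"] == pytest.approx(1.0, abs=1e-9)

    def test_near_duplicate_exceeds_threshold(self):
        rng = np.random.default_rng(17)
        x1 = rng.normal(size=300)
        X = pd.DataFrame({"(Intercept)": 1.0, "x1": x1,
                          "x2": x1 + 1e-4 * rng.normal(size=300)})
        vifs = mm.gvif(X, {"x1": ["x1"], "x2": ["x2"]})
        assert vifs["x1"] > 10 and vifs["x2"] > 10

    def test_balanced_categorical_orthogonal_design(self):
        n = 120
        lev = np.tile(["a", "b", "c"], n // 3)
        x = np.tile([1.0, -1.0], n // 2)
        tbl = pd.DataFrame({"g": lev, "x": x})
        X, groups = mm._expand_terms(("g", "x"), tbl, {}, [])
        vifs = mm.gvif(X, groups)
        assert vifs["g"] == pytest.approx(1.0, abs=1e-6)

    def test_exact_alias_is_singular(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"(Intercept)": 1.0, "x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            mm.gvif(X, {"x1": ["x1"], "x2": ["x2"]})


@pytest.fixture(scope="module")
def rich_metrics(species_rich_study):
    from mastgrad.metrics import metrics_table
    from mastgrad.timeseries_io import apply_study_filters, group_species

    return metrics_table(
        apply_study_filters(group_species(species_rich_study.series)))


class TestSpeciesSpecific:
    def test_minimum_series_enforced(self, rich_metrics, species_rich_study):
        sp = rich_metrics["species_group"].iloc[0]
        with pytest.raises(ValueError, match="series"):
            mm.fit_species_specific(
                mm.ModelSpec(response="psd"), rich_metrics,
                species_rich_study.climate, species_rich_study.range_cells, sp,
                min_series=1000)

    def test_single_method_species_drops_term(self, rich_metrics, species_rich_study):
        sp = rich_metrics["species_group"].iloc[0]
        forced = rich_metrics.copy()
        forced.loc[forced["species_group"] == sp, "collection_method"] = "seed_trap"
        fit = mm.fit_species_specific(
            mm.ModelSpec(response="psd"), forced, species_rich_study.climate,
            species_rich_study.range_cells, sp)
        assert "collection_method" in fit.design.dropped_terms
        assert not any(c.startswith("collection_method[") for c in fit.x_columns)

    def test_collinear_covariate_auto_dropped(self, rich_metrics, species_rich_study):
        sp = rich_metrics["species_group"].iloc[0]
        rigged = rich_metrics.copy()
        sub = rigged["species_group"] == sp
        # series length nearly encodes the collection method: a near-perfect
        # numeric proxy, GVIF^(1/(2df)) far beyond 10
        rng = np.random.default_rng(1)
        code = rigged.loc[sub, "collection_method"].map(
            {"count": 10.0, "harvest": 25.0, "seed_trap": 40.0})
        rigged["n_years"] = rigged["n_years"].astype(float)
        rigged.loc[sub, "n_years"] = code + 1e-4 * rng.normal(size=sub.sum())
        fit = mm.fit_species_specific(
            mm.ModelSpec(response="psd"), rigged, species_rich_study.climate,
            species_rich_study.range_cells, sp)
        kept = {t for t in ("n_years", "collection_method")
                if any(c == t or c.startswith(t + "[") for c in fit.x_columns)}
        assert len(kept) <= 1  # the collinear pair cannot both survive

    def test_quadratic_sign_recovered_single_species(self, rich_metrics, species_rich_study):
        # generator plants a concave MAT effect on Psd; check each species' fit
        negatives = 0
        species = rich_metrics["species_group"].unique()
        for sp in species:
            fit = mm.fit_species_specific(
                mm.ModelSpec(response="psd"), rich_metrics,
                species_rich_study.climate, species_rich_study.range_cells, sp)
            assert fit.converged
            negatives += fit.coefficients.loc["mat^2", "estimate"] < 0
        assert negatives >= len(species) - 1


class TestResidualCheck:
    def test_well_specified_model_passes_ks(self, small_study):
        from mastgrad.pipeline import fit_study_model

        fit, _ = fit_study_model(small_study, "psd")
        d, p = mm.residual_ks_check(fit, seed=3)
        assert 0 <= d <= 1
        assert p > 0.001  # no gross distributional misfit
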