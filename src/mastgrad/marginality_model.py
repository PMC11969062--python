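"""Subject-centered climate-marginality regression models.

The response (one masting metric per series) is modelled as Gaussian with a
quadratic climate surface in the mean and a log-linear model for the residual
standard deviation:

    y_i ~ Normal(x_i' beta, sigma_i^2),      log sigma_i = z_i' gamma

The mean design holds the climate terms (annual flavor: MAT, AP, MAT×AP,
MAT², AP²; seasonal flavor: the same structure for hottest- and coldest-
quarter temperature and precipitation), series length, the categorical
reproductive variable and collection method, and — for the AR(1) response —
latitude. The dispersion design holds species group, collection method and
reproductive variable (treatment-coded, additive on log-sd).

(beta, gamma) are estimated jointly by maximum likelihood (BFGS with analytic
gradient, followed by an exact WLS/Newton polish); standard errors come from
the inverse observed information, Wald z uses the normal reference. Linear
climate effects are judged with likelihood-ratio tests that first strip the
focal variable's quadratic and interaction terms ("full" model) and then its
linear term ("reduced" model). Collinearity is screened with generalized
variance inflation factors, reported as GVIF^(1/(2 df)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .climate import CLIMATE_VARS, CenteredDesign, range_medians

logger = logging.getLogger("mastgrad")

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "LRTResult",
    "annual_spec",
    "seasonal_spec",
    "build_design",
    "fit_hetero_gaussian",
    "fit_model",
    "lrt_linear_term",
    "gvif",
    "fit_species_specific",
    "residual_ks_check",
]

ANNUAL_CLIMATE_TERMS = ("mat", "ap", "mat:ap", "mat^2", "ap^2")
SEASONAL_CLIMATE_TERMS = (
    "t_hq", "p_hq", "t_hq:p_hq", "t_hq^2", "p_hq^2",
    "t_cq", "p_cq", "t_cq:p_cq", "t_cq^2", "p_cq^2",
)
DEFAULT_COVARIATES = ("n_years", "variable_class", "collection_method")
DEFAULT_DISPERSION = ("species_group", "collection_method", "variable_class")

_MAX_LOG_SD = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Description of one marginality model.

    ``mean_terms`` are term names over centered(-scaled) columns: a bare name
    is linear, ``a:b`` an interaction, ``a^2`` a quadratic, and a categorical
    column name expands to treatment-coded dummies. ``include_latitude``
    defaults to True exactly for the AR(1) response (its residuals trend with
    latitude otherwise).
    """

    response: str
    flavor: str = "annual"
    mean_terms: tuple[str, ...] = ()
    dispersion_terms: tuple[str, ...] = DEFAULT_DISPERSION
    include_latitude: bool | None = None

    def __post_init__(self):
        if self.flavor not in ("annual", "seasonal"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if not self.mean_terms:
            climate = ANNUAL_CLIMATE_TERMS if self.flavor == "annual" else SEASONAL_CLIMATE_TERMS
            object.__setattr__(self, "mean_terms", climate + DEFAULT_COVARIATES)
        if self.include_latitude is None:
            object.__setattr__(self, "include_latitude", self.response == "ar1")
        if self.include_latitude and "latitude" not in self.mean_terms:
            object.__setattr__(self, "mean_terms", self.mean_terms + ("latitude",))

    @property
    def climate_terms(self) -> tuple[str, ...]:
        return ANNUAL_CLIMATE_TERMS if self.flavor == "annual" else SEASONAL_CLIMATE_TERMS

    @property
    def linear_climate_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.climate_terms
                     if ":" not in t and "^" not in t and t in self.mean_terms)


def annual_spec(response: str, **kw) -> ModelSpec:
    return ModelSpec(response=response, flavor="annual", **kw)


def seasonal_spec(response: str, **kw) -> ModelSpec:
    return ModelSpec(response=response, flavor="seasonal", **kw)


@dataclass
class Design:
    """Design matrices plus bookkeeping for GVIF, LRT and surface prediction."""

    X: pd.DataFrame
    Z: pd.DataFrame
    y: np.ndarray
    term_groups: dict[str, list[str]]
    cat_levels: dict[str, list[str]]
    dropped_terms: list[str] = field(default_factory=list)
    n_dropped_rows: int = 0


def _term_column(term: str, table: pd.DataFrame) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        return table[a].to_numpy(float) * table[b].to_numpy(float)
    if term.endswith("^2"):
        base = term[:-2]
        return np.square(table[base].to_numpy(float))
    return table[term].to_numpy(float)


def _expand_terms(
    terms: tuple[str, ...],
    table: pd.DataFrame,
    cat_levels: dict[str, list[str]],
    dropped: list[str],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand term names into columns; returns (matrix, term→columns map)."""
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(table))}
    groups: dict[str, list[str]] = {}
    for term in terms:
        if term in table.columns and table[term].dtype == object:
            levels = cat_levels.setdefault(term, sorted(table[term].astype(str).unique()))
            if len(levels) < 2:
                if term not in dropped:
                    logger.warning("design: single-level categorical %r dropped", term)
                    dropped.append(term)
                continue
            names = []
            vals = table[term].astype(str)
            for lev in levels[1:]:  # alphabetically-first level is the reference
                name = f"{term}[{lev}]"
                cols[name] = (vals == lev).to_numpy(float)
                names.append(name)
            groups[term] = names
        else:
            cols[term] = _term_column(term, table)
            groups[term] = [term]
    X = pd.DataFrame(cols, index=table.index)
    return X, groups


def _check_full_rank(X: pd.DataFrame, label: str) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        from scipy.linalg import qr as _qr

        # pivoted QR: columns pivoted past the numerical rank are aliased
        _, _, piv = _qr(arr, mode="economic", pivoting=True)
        aliased = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"{label} design is rank-deficient; aliased columns: {aliased}")


def build_design(spec: ModelSpec, table: pd.DataFrame) -> Design:
    """Build mean (X) and dispersion (Z) matrices and the response vector.

    The response column is ``<response>_c`` when present (subject-centered
    table) else the raw response column (species-specific mode). Rows with a
    missing response are dropped (listwise, counted).
    """
    resp_col = f"{spec.response}_c" if f"{spec.response}_c" in table.columns else spec.response
    if resp_col not in table.columns:
        raise ValueError(f"response column {resp_col!r} not in table")
    keep = table[resp_col].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing %s", n_dropped, resp_col)
    table = table.loc[keep]

    missing_vars = [
        t for t in spec.mean_terms
        if ":" not in t and not t.endswith("^2") and t not in table.columns
    ]
    if missing_vars:
        raise ValueError(f"model variables missing from table: {missing_vars}")

    cat_levels: dict[str, list[str]] = {}
    dropped: list[str] = []
    X, groups = _expand_terms(spec.mean_terms, table, cat_levels, dropped)
    Z, _ = _expand_terms(
        tuple(t for t in spec.dispersion_terms if t in table.columns),
        table, cat_levels, dropped,
    )
    _check_full_rank(X, "mean")
    _check_full_rank(Z, "dispersion")
    y = table[resp_col].to_numpy(float)
    return Design(X=X, Z=Z, y=y, term_groups=groups, cat_levels=cat_levels,
                  dropped_terms=dropped, n_dropped_rows=n_dropped)


@dataclass
class FitResult:
    """Maximum-likelihood fit of the heteroscedastic Gaussian model."""

    coefficients: pd.DataFrame       # index term-column; estimate, se, z, p
    dispersion: pd.DataFrame         # index term-column; estimate (log-sd), se
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    cov: np.ndarray                  # joint (beta, gamma) covariance
    x_columns: list[str]
    z_columns: list[str]
    optimizer_report: str = ""
    design: Design | None = None
    spec: ModelSpec | None = None

    @property
    def beta(self) -> np.ndarray:
        return self.coefficients["estimate"].to_numpy()

    @property
    def gamma(self) -> np.ndarray:
        return self.dispersion["estimate"].to_numpy()

    def beta_cov(self) -> np.ndarray:
        p = len(self.x_columns)
        return self.cov[:p, :p]


def _loglik_parts(theta, X, Z, y, p):
    beta, gamma = theta[:p], theta[p:]
    mu = X @ beta
    log_sd = np.clip(Z @ gamma, -_MAX_LOG_SD, _MAX_LOG_SD)
    sd = np.exp(log_sd)
    r = y - mu
    u = np.square(r / sd)
    ll = -0.5 * len(y) * np.log(2 * np.pi) - log_sd.sum() - 0.5 * u.sum()
    return ll, r, sd, u


def _neg_loglik_and_grad(theta, X, Z, y, p):
    ll, r, sd, u = _loglik_parts(theta, X, Z, y, p)
    g_beta = X.T @ (r / sd**2)
    g_gamma = Z.T @ (u - 1.0)
    return -ll, -np.concatenate([g_beta, g_gamma])


def _observed_information(theta, X, Z, y, p):
    _, r, sd, u = _loglik_parts(theta, X, Z, y, p)
    w = 1.0 / sd**2
    i_bb = X.T @ (X * w[:, None])
    i_bg = 2.0 * X.T @ (Z * (r * w)[:, None])
    i_gg = 2.0 * Z.T @ (Z * u[:, None])
    top = np.hstack([i_bb, i_bg])
    bot = np.hstack([i_bg.T, i_gg])
    return np.vstack([top, bot])


def _polish(theta, X, Z, y, p, max_iter=200, tol=1e-9):
    """Alternate exact WLS for beta with Newton steps (step-halving) for gamma."""
    theta = theta.copy()
    for _ in range(max_iter):
        beta, gamma = theta[:p], theta[p:]
        log_sd = np.clip(Z @ gamma, -_MAX_LOG_SD, _MAX_LOG_SD)
        w = np.exp(-2.0 * log_sd)
        Xw = X * w[:, None]
        beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        theta[:p] = beta

        ll, r, sd, u = _loglik_parts(theta, X, Z, y, p)
        g = Z.T @ (u - 1.0)
        H = 2.0 * Z.T @ (Z * u[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = theta.copy()
            cand[p:] = gamma + scale * step
            ll_new = _loglik_parts(cand, X, Z, y, p)[0]
            if ll_new >= ll - 1e-12:
                theta = cand
                break
            scale *= 0.5
        _, grad = _neg_loglik_and_grad(theta, X, Z, y, p)
        if np.max(np.abs(grad)) < tol:
            break
    return theta


def fit_hetero_gaussian(
    X,
    Z,
    y,
    tol: float = 1e-6,
    n_restarts: int = 2,
    seed: int = 0,
) -> FitResult:
    """Jointly maximise the heteroscedastic Gaussian likelihood over (β, γ).

    Starts from the OLS solution for β with γ = (log residual sd, 0, …);
    quasi-Newton (BFGS, analytic gradient) followed by an exact WLS/Newton
    polish. Jittered restarts (fixed seed) guard against bad starts.
    Standard errors come from the inverse observed information; Wald z uses
    the standard normal reference.
    """
    x_cols = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(np.shape(X)[1])]
    z_cols = list(Z.columns) if hasattr(Z, "columns") else [f"z{i}" for i in range(np.shape(Z)[1])]
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    q = Z.shape[1]

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sd0 = max(float(np.sqrt(np.mean(resid**2))), 1e-8)
    gamma0 = np.zeros(q)
    gamma0[0] = np.log(sd0)
    start = np.concatenate([beta0, gamma0])

    rng = np.random.default_rng(seed)
    best, best_ll, report = None, -np.inf, []
    # attempt 0: exact WLS / Newton alternation from the OLS start (fast and
    # reliable on well-posed problems); later attempts add BFGS + jitter
    for attempt in range(2 + n_restarts):
        try:
            if attempt == 0:
                theta = _polish(start.copy(), X, Z, y, p)
            else:
                x0 = start if attempt == 1 else start + rng.normal(scale=0.2, size=start.size)
                res = optimize.minimize(
                    _neg_loglik_and_grad, x0, args=(X, Z, y, p),
                    method="BFGS", jac=True,
                    options={"gtol": 1e-8, "maxiter": 500},
                )
                theta = _polish(res.x, X, Z, y, p)
        except (np.linalg.LinAlgError, ValueError):
            report.append(f"attempt {attempt}: linear algebra failure")
            continue
        ll, grad = _neg_loglik_and_grad(theta, X, Z, y, p)
        ll = -ll
        gnorm = float(np.max(np.abs(grad)))
        report.append(f"attempt {attempt}: loglik={ll:.6f} max|grad|={gnorm:.2e}")
        if np.isfinite(ll) and ll > best_ll:
            best, best_ll, best_gnorm = theta, ll, gnorm
        if np.isfinite(ll) and gnorm < tol:
            break

    converged = best is not None and best_gnorm < tol
    if best is None:
        best = start
        best_ll = float(_loglik_parts(start, X, Z, y, p)[0])

    info = _observed_information(best, X, Z, y, p)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p + q, p + q), np.nan)
        se = np.full(p + q, np.nan)
        converged = False

    beta, gamma = best[:p], best[p:]
    if converged:
        zval = beta / se[:p]
        pval = 2.0 * stats.norm.sf(np.abs(zval))
    else:
        zval = np.full(p, np.nan)
        pval = np.full(p, np.nan)
    coef = pd.DataFrame(
        {"estimate": beta, "se": se[:p], "z": zval, "p": pval}, index=x_cols
    )
    disp = pd.DataFrame({"estimate": gamma, "se": se[p:]}, index=z_cols)
    return FitResult(
        coefficients=coef, dispersion=disp, loglik=best_ll,
        n_obs=n, n_params=p + q, converged=converged, cov=cov,
        x_columns=x_cols, z_columns=z_cols,
        optimizer_report="; ".join(report),
    )


def fit_model(spec: ModelSpec, centered: CenteredDesign | pd.DataFrame, **fit_kw) -> FitResult:
    """Build the design from a centered table and fit; attaches design + spec."""
    table = centered.table if isinstance(centered, CenteredDesign) else centered
    design = build_design(spec, table)
    fit = fit_hetero_gaussian(design.X, design.Z, design.y, **fit_kw)
    fit.design = design
    fit.spec = spec
    return fit


@dataclass
class LRTResult:
    """Likelihood-ratio test of one linear climate term.

    ``full`` is the model with the focal variable's quadratic and interaction
    terms removed but its linear term kept; ``reduced`` also removes the
    linear term. One parameter difference, so the statistic is chi-squared
    with 1 df under the null.
    """

    focal_term: str
    full_loglik: float
    reduced_loglik: float
    statistic: float
    df: int
    p: float
    valid: bool = True


def _strip_focal(terms: tuple[str, ...], focal: str, drop_linear: bool) -> tuple[str, ...]:
    out = []
    for t in terms:
        if t == f"{focal}^2":
            continue
        if ":" in t and focal in t.split(":"):
            continue
        if drop_linear and t == focal:
            continue
        out.append(t)
    return tuple(out)


def lrt_linear_term(
    spec: ModelSpec,
    table: CenteredDesign | pd.DataFrame,
    focal: str,
    **fit_kw,
) -> LRTResult:
    """Likelihood-ratio test for the independent contribution of one linear
    climate predictor, comparing the focal-stripped "full" model to the
    "reduced" model without the focal linear term."""
    if focal not in spec.linear_climate_terms:
        raise ValueError(f"{focal!r} is not a linear climate term of this model")
    tbl = table.table if isinstance(table, CenteredDesign) else table

    full_spec = replace(spec, mean_terms=_strip_focal(spec.mean_terms, focal, drop_linear=False))
    red_spec = replace(spec, mean_terms=_strip_focal(spec.mean_terms, focal, drop_linear=True))
    if full_spec.mean_terms == red_spec.mean_terms:
        raise ValueError(f"focal term {focal!r} absent from the model")

    full = fit_model(full_spec, tbl, **fit_kw)
    reduced = fit_model(red_spec, tbl, **fit_kw)
    valid = full.converged and reduced.converged
    statistic = 2.0 * (full.loglik - reduced.loglik)
    if statistic < 0:
        if statistic < -1e-6:
            valid = False
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df=1))
    return LRTResult(
        focal_term=focal, full_loglik=full.loglik, reduced_loglik=reduced.loglik,
        statistic=float(statistic), df=1, p=p, valid=valid,
    )


def gvif(X: pd.DataFrame, term_groups: dict[str, list[str]]) -> dict[str, float]:
    """Generalized variance inflation factors, reported as GVIF^(1/(2 df)).

    For each predictor's column group g over the correlation matrix R of the
    non-intercept columns: GVIF = det(R_gg)·det(R_-g-g)/det(R); df is the
    number of columns in the group. A value of 1 means no collinearity.
    """
    cols = [c for c in X.columns if c != "(Intercept)"]
    arr = X[cols].to_numpy(float)
    if arr.shape[1] < 2:
        return {t: 1.0 for t in term_groups}
    R = np.corrcoef(arr, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular correlation matrix; design is aliased")
    idx = {c: i for i, c in enumerate(cols)}
    out = {}
    for term, group_cols in term_groups.items():
        g = [idx[c] for c in group_cols if c in idx]
        if not g:
            continue
        rest = [i for i in range(len(cols)) if i not in g]
        s1, ld1 = np.linalg.slogdet(R[np.ix_(g, g)])
        if rest:
            s2, ld2 = np.linalg.slogdet(R[np.ix_(rest, rest)])
        else:
            s2, ld2 = 1.0, 0.0
        if s1 <= 0 or s2 <= 0:
            raise ValueError(f"singular correlation submatrix for term {term!r}")
        log_gvif = ld1 + ld2 - logdet
        df = len(g)
        out[term] = float(np.exp(log_gvif / (2.0 * df)))
    return out


def fit_species_specific(
    spec: ModelSpec,
    metrics: pd.DataFrame,
    climate: pd.DataFrame,
    range_cells: pd.DataFrame,
    species_group: str,
    min_series: int = 30,
    gvif_threshold: float = 10.0,
    min_dispersion_obs: int | None = None,
    **fit_kw,
) -> FitResult:
    """Fit one species' marginality model.

    Climate variables are centered on the species' range median (unscaled);
    the response and the non-climate numeric covariates stay on their raw
    scales. Single-level categoricals are dropped, and any non-climate
    predictor whose GVIF^(1/(2 df)) exceeds ``gvif_threshold`` is removed
    (worst first) before the final fit. Species cannot enter the dispersion
    model here, so dispersion varies with collection method and reproductive
    variable only; dispersion-factor levels with fewer than
    ``min_dispersion_obs`` series (default: mean-model parameter count + 2)
    are pooled with the factor's modal level — the mean model can interpolate
    a smaller cell exactly, sending its log-sd to −∞ and the likelihood to +∞.
    """
    sub = metrics[metrics["species_group"] == species_group].copy()
    if len(sub) < min_series:
        raise ValueError(
            f"{species_group}: {len(sub)} series < required {min_series}"
        )
    med = range_medians(range_cells, species_group).loc[species_group]
    table = sub.merge(climate, on="site_id", how="left", validate="many_to_one")
    for var in CLIMATE_VARS:
        table[var] = table[var] - med[var]

    if min_dispersion_obs is None:
        mean_only = replace(spec, dispersion_terms=())
        n_mean_params = build_design(mean_only, table).X.shape[1]
        min_dispersion_obs = n_mean_params + 2

    disp = []
    for term in spec.dispersion_terms:
        if term == "species_group" or term not in table.columns:
            continue
        counts = table[term].value_counts()
        rare = counts.index[counts < min_dispersion_obs]
        if len(rare):
            pooled = table[term].where(~table[term].isin(rare), counts.idxmax())
            logger.warning(
                "%s: dispersion levels %s of %r pooled into %r (< %d series)",
                species_group, list(rare), term, counts.idxmax(), min_dispersion_obs,
            )
            table[f"{term}_disp"] = pooled
            disp.append(f"{term}_disp")
        else:
            disp.append(term)
    sp = replace(spec, dispersion_terms=tuple(disp))

    while True:
        design = build_design(sp, table)
        vifs = gvif(design.X, design.term_groups)
        offenders = {
            t: v for t, v in vifs.items()
            if v > gvif_threshold and t not in sp.climate_terms
        }
        if not offenders:
            break
        worst = max(offenders, key=offenders.get)
        logger.warning(
            "%s: predictor %r removed, GVIF^(1/2df)=%.1f > %.0f",
            species_group, worst, offenders[worst], gvif_threshold,
        )
        sp = replace(sp, mean_terms=tuple(t for t in sp.mean_terms if t != worst))

    fit = fit_hetero_gaussian(design.X, design.Z, design.y, **fit_kw)
    fit.design = design
    fit.spec = sp
    return fit


def residual_ks_check(fit: FitResult, n_sims: int = 250, seed: int = 0) -> tuple[float, float]:
    """Simulated-residual distribution check (KS test of PIT residuals).

    Simulates ``n_sims`` response sets from the fitted model, computes the
    probability-integral-transform residual of each observation against its
    simulated distribution (rank-randomised), and KS-tests the PITs against
    uniform. Returns (D, p). A small p flags distributional misfit.
    """
    if fit.design is None:
        raise ValueError("fit carries no design; use fit_model")
    X = fit.design.X.to_numpy(float)
    Z = fit.design.Z.to_numpy(float)
    y = fit.design.y
    mu = X @ fit.beta
    sd = np.exp(np.clip(Z @ fit.gamma, -_MAX_LOG_SD, _MAX_LOG_SD))
    rng = np.random.default_rng(seed)
    sims = mu[:, None] + sd[:, None] * rng.standard_normal((len(y), n_sims))
    below = (sims < y[:, None]).sum(axis=1)
    ties = (sims == y[:, None]).sum(axis=1)
    u = (below + rng.uniform(size=len(y)) * (ties + 1)) / (n_sims + 1)
    d, p = stats.kstest(u, "uniform")
    return float(d), float(p)
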