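# Methods

## Scope

`mastgrad` implements a complete analysis chain for intraspecific masting
variation across climate-marginality gradients: inclusion filtering of
long-format seed-crop records, per-series masting statistics, climate
preparation and subject-centering, pooled and species-specific heteroscedastic
regression with Wald and likelihood-ratio inference, GVIF collinearity
screening, hull-masked response surfaces, and a synthetic-study generator that
plants known effect surfaces so every stage can be validated against truth.
Climate arrives as tables (site climate and per-species range cells); raster
extraction and range-polygon processing are out of scope.

## Record filtering

A series enters the analysis if its unit class is quantitative (ordinal,
index and synchrony-based units are excluded), its spatial scale is stand or
patch, it has at least 10 observed years, and its species group is observed
at at least 10 distinct sites. The filters apply in that order, so the site
count refers only to series that are themselves analysable; both thresholds
are inclusive. A "site" is a distinct site identifier — several series at one
site count once. *Quercus robur* and *Q. petraea* are pooled into one group
by default (they hybridize and mast in synchrony); the grouping map is
configurable. Gap years inside a series are allowed; `n_years` counts
observed years. Duplicate (series, year) rows are a hard error rather than
being silently averaged.

## Masting statistics

For annual crops `x_1..x_n`:

- **CVp** `= sd(x)/mean(x)` with the sample sd (n−1). Undefined (flagged
  missing) for zero-mean series or fewer than 2 years.
- **kCVp** `= sqrt(CVp²/(1+CVp²))`, a bounded transform of CVp; its exact
  inverse `CVp = kCVp/sqrt(1−kCVp²)` is also provided.
- **AR(1)**: `r1 = Σ_{t<n}(x_t−x̄)(x_{t+1}−x̄) / Σ_t(x_t−x̄)²` — the
  divisor-n autocovariance convention used by the standard ACF estimator,
  which differs from the (n−1)-pairs convention at small n. Missing for
  zero-variance series. Series with calendar gaps are treated as consecutive
  observations, with a warning.
- **Psd**: standardized deviates `d_t = (x_t−x̄)/s` (sample sd); the
  threshold is the magnitude of the largest deviate below the mean,
  `T = |min d_t|`; year t is a mast year iff `d_t > T`, strictly — a tie at
  exactly T is not a mast year. Psd is the mast-year fraction; a constant
  series has Psd 0.

All four are checked against independent brute-force implementations in the
test suite.

## Climate preparation and centering

Temperatures (never precipitation) are lapse-rate adjusted by
`T − λ·(series elevation − grid elevation)/100` with λ = 0.65 °C/100 m when
both elevations are known. The species' core climate is the unweighted
per-cell median over its range-climate table (midpoint convention for even
counts).

Subject-centering uses two schemes: responses and non-climate numeric
covariates (series length, latitude) are centered on species means; climate
variables are centered on the species range median, so the centered value is
the site's climatic marginality with sign. Numeric predictors are then
divided by their root mean square `sqrt(mean(x²))`, pooled across species and
computed after centering; the response is centered but never scaled.
Quadratic and interaction columns are built afterwards from the scaled linear
columns (squares and products are not independently re-scaled), which keeps
the fitted surfaces interpretable in the scaled units. The centering
constants and scales are exported as a JSON sidecar so predictions can be
mapped back to natural units.

## Regression model

Each metric is modelled as Gaussian with a log-linear dispersion submodel:

    y_i ~ Normal(x_i'β, σ_i²),   log σ_i = z_i'γ.

Mean terms, annual flavor: MAT, AP, MAT×AP, MAT², AP²; seasonal flavor: the
same structure for hottest- and coldest-quarter temperature and
precipitation (10 climate terms). Covariates: series length, reproductive
variable (cone/fruit/seed) and collection method (seed trap/count/harvest) as
treatment-coded factors with the alphabetically first level as reference;
subject-centered latitude enters the AR(1) models only (their residuals
otherwise trend with latitude). The dispersion design holds species group,
collection method and reproductive variable, additive on log-sd with no
interactions — the parsimonious reading, and equivalent up to a factor 2 on γ
to a log-variance link. No random effects: centering removes the average
species effect by construction. Single-level factors are dropped with a
warning; rank-deficient designs are a hard error naming the aliased columns.

(β, γ) are estimated by joint maximum likelihood. The optimizer alternates
exact weighted-least-squares updates for β with Newton steps (step-halving)
for γ from an OLS start, falling back to BFGS with the analytic gradient plus
two jittered restarts (fixed seed) if the alternation stalls; convergence is
declared at gradient max-norm < 1e−6. With an intercept-only dispersion
design the optimum coincides with OLS plus the divisor-n ML variance, which
the tests assert to 1e−6. Standard errors come from the inverse *observed*
information (analytic Hessian, verified against numerical differentiation);
Wald z uses the normal reference. Rows with a missing response are dropped
listwise and counted.

Because Wald p-values for linear terms are conditional on the quadratic and
interaction terms, linear climate effects are assessed by likelihood-ratio
tests: the "full" model removes the focal variable's quadratic and every
interaction containing it while keeping its linear term; the "reduced" model
removes the linear term too; the statistic `2(ℓ_full − ℓ_reduced)` is
referred to χ²₁ (negative values above −1e−6 are clipped to zero; larger
negatives flag a failed fit).

Collinearity is screened with generalized variance inflation factors over the
correlation matrix R of the non-intercept columns:
`GVIF = det(R₁₁)·det(R₂₂)/det(R)` per predictor's column group, reported as
`GVIF^(1/(2df))` with 10 as the removal threshold.

**Species-specific mode** fits the same machinery to one species (default
minimum 30 series): climate is centered on the range median but not scaled,
non-climate variables stay raw, species leaves the dispersion model,
single-level factors are dropped, and non-climate predictors exceeding the
GVIF threshold are removed worst-first. Dispersion-factor levels with fewer
observations than the mean-model parameter count + 2 are pooled into the
factor's modal level: the mean model can interpolate a smaller cell exactly,
sending its log-sd to −∞ and the likelihood to +∞ — a real degeneracy of
heteroscedastic ML at small n, not an optimizer failure.

**Residual check.** Instead of a full simulation-based residual diagnostic
suite, the package simulates 250 response sets from the fitted model,
computes each observation's rank-randomised probability integral transform
against its simulated distribution, and KS-tests the PITs against uniform,
reporting D and p.

## Synthetic studies

The generator emulates the structure of a MASTREE+-scale corpus: 19 species ×
23 sites ≈ 437 series by default, series lengths 10 + a geometric excess
clipped at 62 years (mean ≈ 18.5), species-specific climate centroids with
range cells and sites drawn uniformly within ±span of the centroid (MAT span
4 °C, AP span 350 mm), quarter variables constructed to satisfy
t_cq ≤ MAT ≤ t_hq, and method/variable labels drawn from realistic mixes.

One series is an AR(1) latent log-baseline plus multiplicative mast events:

    b_t = μ + φ(b_{t−1} − μ) + ε_t,  ε ~ N(0, τ²);   x_t = e^{b_t}(1 + (M−1)m_t),
    m_t ~ Bernoulli(p_m)

with defaults φ = 0.2, τ = 0.5, p_m = 0.2, M = 6 — chosen so the default
corpus lands in the empirically typical ranges of the metrics (species-mean
CVp ≈ 0.9–1.2, Psd ≈ 0.12–0.16, mostly negative AR(1)). The three dials are
deliberately separable: M and τ move CVp, φ and mast spacing move AR(1), p_m
moves Psd. Site-level p_m and M are deterministic functions of the site's
standardized centered climate z = (site − range median)/span through the
configured true effects: by default `logit p_m` carries −1.0·z_MAT² (mast
years rarest at both margins) and `log M` carries −0.35·z_MAT (smaller mast
events, hence lower CVp, toward the warm margin). All randomness flows from
one root generator (default seed 20250403); a fixed seed reproduces the CSVs
byte-for-byte.

What the generator does *not* emulate: spatial autocorrelation between sites,
inter-series synchrony within species, observation error specific to a
collection method, trends or climate change within series, and unequal series
counts per site. Passing tests therefore demonstrate that the estimators and
inference machinery recover planted effects under a realistic but idealized
data-generating process — not that the substantive conclusions would hold on
any particular real corpus.

A second, metric-level generator draws responses directly from the regression
model itself on a study-shaped design (`simulate_metric_table`). It exists
because coefficient-recovery and interval-coverage experiments need an exact
truth for the fitted estimand: the series-level generator maps its logit- and
log-scale effects onto the metric scale nonlinearly, so no exact coefficient
truth exists for the full pipeline, which is instead validated by
sign-replication of the planted pattern across whole simulated studies.

## Validation experiment sizes

The experiments module fixes the problem sizes used by the test suite and the
reporting script: 1000 random series for metric-oracle agreement, 50 random
fixtures for the homoscedastic limit, n = 2000 for dispersion recovery, 500
null replicates at the default study conditions for LRT type-I calibration,
200 replicates for coefficient recovery/coverage, and 100 full studies for
pattern sign-replication. All use the package's canonical seed by default.

## Known limitations and numerical choices

- Wald intervals are mildly anti-conservative at the default study scale:
  with 23 dispersion parameters estimated from ~23 series per species, ML
  log-sd estimates are biased low and feasible-GLS adds variance, so SEs run
  ~4% small and 95% intervals cover ≈ 93% in the recovery scenario. The
  likelihood-ratio statistic for linear terms is inflated ~14% for the same
  reason (type-I ≈ 0.065 at α = 0.05). This is a property of the ML
  estimator, not the optimizer; it is why linear climate effects should be
  judged by the LRT (already slightly liberal) rather than Wald p, and why
  both are reported.
- `log σ` is clipped to ±30 inside the likelihood to avoid overflow; the clip
  is never active at a legitimate optimum.
- Mast-year ties at exactly the threshold are not mast years (strict rule);
  the indicator is floating-point sensitive on knife-edge ties, which the
  property tests skip explicitly.
- Convex hulls are closed: observed points on the boundary are inside. The
  default surface grid is 101×101 over the observed range with no padding.
- Missing elevations leave temperatures unadjusted (logged), and missing
  metric values propagate as flagged-missing rows that are dropped per model.
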