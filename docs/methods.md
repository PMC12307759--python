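# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind the package. It is the reference for
*why* things are the way they are; the README shows *how* to use them.

## Temporal weighting and the development typology

Country development profiles are built from three indicators: GDP per
capita (USD), GDP growth rate (%), and health expenditure per capita
(USD). Because year coverage is irregular and older records would
otherwise dominate long series, each country's indicator values are
averaged with normalized exponential weights
`w_t ∝ exp(λ·(t − min t))` over that country's observed years. λ ≥ 0 is
a decay rate per year: λ = 0 gives the exact uniform average (implemented
as a special case, not as a limit of the formula), and consecutive
observed years always satisfy `w_{t+1}/w_t = e^λ`. Exponentials are
computed relative to the latest year so large λ cannot overflow. Weights
are renormalized per indicator over that indicator's non-missing years,
so every weighted mean is a convex combination of observed values. A
country missing an entire indicator cannot be placed in the feature space
and is dropped from clustering with a log entry — never imputed.

Profiles are z-standardized per indicator across countries before
K-means; raw USD scales would otherwise dwarf the growth-rate axis in the
Euclidean metric. Standardizing before K-means is a convention analysts
differ on, so the flag is exposed (`standardize=True` by default) and
results can be reported under either convention.

Clustering is Lloyd's K-means, best of 50 restarts. k-means++ seeds
centers at data points; on very small inputs the global WCSS optimum can
be Voronoi-consistent yet unreachable from any data-point start (we hold
a 7-point instance where thousands of k-means++ restarts fail), so a
second batch of seeded restarts initialized uniformly in the data
bounding box is always run and the best model kept. This makes the fitter
agree with an exhaustive-partition oracle on every small instance we test
while leaving large-instance behaviour unchanged. Everything is
deterministic given the seed.

Cluster naming follows a fixed alignment rule: the cluster with the
highest GDP-per-capita centroid is "developed", the next "developing",
then `cluster_3`… This makes agreement rates between configurations well
defined for k = 2 without combinatorial matching. The suggested cluster
count per λ is the silhouette argmax over k ∈ {2,…,6}; the WCSS elbow
curve (non-increasing in k, enforced by extra restarts) is reported as
complementary evidence. Mean silhouette width is averaged over points
(equivalently over countries, one point each); singleton clusters score 0.

The λ-sensitivity grid re-weights, re-standardizes and re-clusters at
each λ on a default grid of 0.00–0.50 in steps of 0.05, records the
suggested k and silhouettes, and scores label agreement against a
reference λ (default 0.20). `select_configuration` returns the λ with the
highest k = 2 silhouette among grid rows whose suggested k is 2, ties
breaking toward the smaller λ (less down-weighting of history, stable
under grid reordering). Countries whose label varies anywhere on the grid
are reported as borderline, with the λ values and direction of each flip
and their profile against both centroids.

## The random-intercept model

Per stratum (commodity group or supply-chain stage) the model is a
Gaussian linear mixed model on the raw percentage scale:

    FLP_ct = β0 + β1·developing_c + β2·(year_t − 2000) + u_c + ε_ct,
    u_c ~ N(0, σ_u²),  ε ~ N(0, σ_e²)

with developed as the reference category and the year covariate centered
at 2000 (centering is applied inside the modelling layer only; shifting
the centering year changes β0 by slope·shift and nothing else, which is
tested). No link function or transform is used: coefficients are
percentage points, directly comparable across strata.

Estimation is maximum likelihood (not REML). The likelihood is profiled
over the variance ratio θ = σ_u²/σ_e²: per country the marginal
covariance block is I + θJ, whose inverse is closed-form
(Sherman–Morrison), so β comes from GLS and σ_e² from the normalized GLS
residual quadratic form at each θ. The one-dimensional profiled
likelihood is maximized in log θ by a 73-knot bracket scan on
log θ ∈ [−10, 8] followed by bounded Brent refinement; θ = 0 (ordinary
least squares) is always evaluated explicitly and returned, flagged as a
boundary fit, when it is at least as good. Degenerate inputs are handled
explicitly: an exactly-fitting dataset (residual variance below 1e−12 of
the response variance) returns the OLS coefficients with
σ_u = σ_e = 0 and a boundary flag; a single-country stratum raises
(the random intercept is unidentifiable); in batch fitting such failures
are logged per stratum without aborting the run.

Wald inference uses cov(β̂) = σ̂_e²(XᵀV₀⁻¹X)⁻¹. p-values use the normal
approximation to t = β̂/SE by default; a residual-df Student-t variant is
available (`df_method="residual"`) because the df convention affects
small-sample p-values in the third decimal. Hypothesis reporting tests
β1 = 0 (no development-group difference) and β2 = 0 (no year trend)
two-sided at α = 0.05 with the direction of any rejected effect.

Variance explained follows Nakagawa–Schielzeth:
R²ₘ = var_f/(var_f + σ_u² + σ_e²) and
R²꜀ = (var_f + σ_u²)/(var_f + σ_u² + σ_e²), where var_f is the
population variance of the fixed-effect predictor over the estimation
sample; 0 ≤ R²ₘ ≤ R²꜀ ≤ 1 always, with equality when σ_u = 0.

## Screening

Raw commodity and activity labels are mapped to 11 commodity groups and
8 activity groups through two-column CSV maps shipped as data, because no
canonical public mapping exists: the default covers the synthetic
vocabulary plus common FAO-style names and is explicitly a user-editable
stand-in. Unmapped labels are kept (group left absent) and reported.

The missingness report counts missing fractions per field (commodity
label, activity label, FLP), coverage per year and country, and
observation counts per group×group cell. Exclusions run in two steps with
counts that must reconcile exactly: (1) groups failing a coverage rule —
default ≥ 30 observations, ≥ 3 distinct countries, ≥ 3 distinct years,
explicit because no published thresholds exist — are dropped wholesale;
(2) listwise deletion removes records missing FLP or either group
assignment. No imputation is performed anywhere: the missingness being
emulated is structural reporting gaps, not random loss, and imputing it
would manufacture information.

## What the synthetic generator emulates — and what it does not

The indicator generator draws each country's persistent mean around its
group centroid (country-level SD), then year values around that mean
(year-level SD), so a random-intercept structure exists in the indicators
themselves; coverage fractions are drawn per country so year sets are
irregular. Defaults are the study conditions: 13 developed countries at
centroid (55,005 USD GDP pc; 5,540 USD health pc; 1.58% growth) and 92
developing at (4,869; 259; 3.19%). Within-group spreads have no published
values and are this package's choice, fixed once: country-level SDs
(6,000; 700; 0.8) / (1,500; 80; 1.0) and year-level SDs (2,500; 250; 1.0)
/ (600; 40; 1.5) for developed/developing — dispersed enough to be
non-trivial, separated enough (~8:1 between-centroid to within-group
distance on the monetary axes) that the true grouping is recoverable,
which is what the recovery tests then verify. GDP and health values are
floored at zero (draws below zero are vanishingly rare at these spreads).

The FLP generator implements the random-intercept model exactly, with
per-stratum (β0, β1, β2) defaulting to the fitted table values for the
10 commodity groups and 8 activity groups. Default σ_u = 2.0 and
σ_e = 2.5: several fitted cell means (e.g. oilseeds × developing) sit
within a point or two of zero, so larger, nominally more realistic
spreads would truncate heavily at the [0, 100] boundary and invalidate
the Gaussian theory the recovery tests rely on. Clipping still occurs in
those near-zero cells (a few percent of records overall) and the count is
always returned. Structural missingness is applied with a logistic ramp
over years (midpoint 2008, scale 3 years), scaled to hit the configured
overall rates — defaults 14.4% commodity, 24% activity, 14.4% FLP — so
gaps concentrate in early years as in real reporting.

Passing tests on this generator therefore show that the pipeline
recovers the structure it assumes; they do not show robustness to what
real FLP data adds: non-Gaussian, boundary-inflated loss distributions,
autocorrelated macro series, crises, reporting-capacity confounding
between missingness and development status, or cross-stratum correlation
beyond the shared country intercept.

## Pipeline and reproducibility

The pipeline runs ingest → screen → classify → sensitivity → fit-mlm →
trends → report in fixed order, one manifest entry per stage with record
counts that reconcile across stages. One master seed fans out to
per-stage seeds via numpy `SeedSequence.spawn`, so identical config+seed
gives byte-identical artifacts. Floating-point artifacts are written at
full precision; rounding happens only in the rendered report, which is
produced purely from saved artifacts and never recomputes a statistic.
The acceptance script (`scripts/acceptance.py`) re-runs the method at the
default conditions with 30 clustering restarts, 5 replicate panels for
the per-stratum coefficient summaries and 100 replicates for interval
coverage — sizes chosen to keep the whole run around ten seconds while
leaving Monte Carlo error well below the effects being measured.

## Known limitations

- The harmonization table and category maps are deliberately small,
  auditable stand-ins; real FAO/World-Bank ingestion will need extending
  both (unmatched names and unmapped labels are reported, not guessed).
- Only a single random intercept is supported: no random slopes, crossed
  effects, or non-Gaussian families. FLP near the 0/100 boundaries will
  violate the Gaussian residual assumption in real data.
- p-values use large-sample approximations; no Satterthwaite or
  Kenward–Roger degrees of freedom.
- Group means and trends weight observations (not countries) by default;
  the country-first alternative is a flag, since either convention is
  defensible and they differ when reporting volume varies by country.
- Model selection across weighting schemes (e.g. AIC comparison of
  time-weighted versus year-covariate specifications) is out of scope.
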