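# Methods

`beechgrow` reimplements, end to end, a continental dendroecological growth
analysis for European beech (*Fagus sylvatica*): ring widths are converted to
annual basal area increments (BAI), a gamma log-link mixed model relates BAI
to long-term aridity, geography and seasonal climate, a nested-model ladder
validates the variable groups, and the fitted model is projected over a
climate grid under delta-shifted emission scenarios with applicability-domain
masking. Because the real 324-site network and the CHELSA/CMIP6 archives are
not redistributable, every quantitative claim the package makes is
demonstrated on synthetic networks generated from the same model family under
known parameters.

## Basal area increment

A tree's BAI in year *t* is the annulus area added at breast height,
`BAI_t = pi (R_t^2 - R_{t-1}^2)` (mm^2/yr). Radii are reconstructed
*outside-in*: the youngest radius is anchored at half the diameter measured
at sampling (DBH) and earlier radii are obtained by subtracting ring widths.
If the pith was missed, the innermost reconstructed radius is positive rather
than the measurement error propagating outward; a DBH smaller than twice the
cumulative width is rejected as geometrically impossible. No classical
detrending is applied — size/age trends are handled inside the model (below).
DBH is treated as bark-free; the package does not guess an over-bark
correction. The canonical working unit is mm^2 throughout (divide by 100 for
cm^2); keeping a single unit internally avoids silent factor-of-100 errors
between figure and text conventions.

Tucson/rwl files are read and written in both common dialects. The writer
defaults to 0.01 mm units with the `999` stop marker and switches the whole
file to the 0.001 mm / `-9999` dialect when any ring is wide enough (>= 9.99
mm) to collide with the stop marker. The reader resolves the dialect per
series: a `-9999` anywhere marks 0.001 mm data (a bare `999` is then a legal
0.999 mm width); otherwise the first `999` terminates 0.01 mm data.

## Climate predictors

Monthly tmax/tmin (deg C) and precipitation (mm) are aggregated to the six
meteorological seasons a ring responds to: previous-year summer (pSUM, JJA of
t-1) and autumn (pAUT, SON of t-1), then winter (WIN: Dec t-1, Jan, Feb),
spring (MAM), summer (JJA) and autumn (SON) of the ring year. Temperatures
are averaged, precipitation summed; seasons with missing months are omitted.
December is assigned to the following year's winter — the standard
dendroclimatic convention. With three climate variables this season set gives
18 seasonal predictors, plus aridity, latitude and altitude: 21 model
variables in total.

Long-term site moisture is the De Martonne aridity index `AI = P / (10 + T)`
(P annual precipitation sum in mm, T annual mean temperature in deg C; annual
mean temperature is taken as the mean of monthly (tmax+tmin)/2). The site
value is the mean of annual AI over 1950-2016 (mean-of-annual-indices, not
the index of mean climate; the two differ slightly and the choice is tested).
Climate classes partition [0, inf) at 10/20/24/28/35/55 with lower-inclusive
half-open intervals (arid, semi-arid, Mediterranean, semi-humid, humid, very
humid, extremely humid); the sources give touching interval labels without
stating inclusivity, so the boundary convention is a documented choice.

## The growth model

For tree *j* at site *i* in year *t*:

    log E[BAI_ijt] = beta0 + log(AI_i) + f(LAT_i) + f(ALT_i)
                     + sum_k [ f(Tmax_itk) + f(Tmin_itk) + log(PP_itk) ]
                     + {AI x geo} + {geo x geo} + {AI, LAT, ALT} x climate
                     + b0_j + b1_j BA_ijt,
    BAI_ijt ~ Gamma(shape, mean = E[BAI_ijt]),   (b0_j, b1_j) ~ N(0, Sigma).

Transforms are applied in the order log -> standardize -> basis expansion,
and every expanded design column is itself standardized (mean 0, SD 1 on the
training rows), so coefficients are comparable across variables; the full
two-stage scaler is stored with the fit and reapplied verbatim to grids and
scenarios. Seasonal precipitation gets a +1 mm offset before the log to guard
dry-season zeros.

The smoothing functions `f(.)` are quadratic polynomials on the standardized
variable (df = 2 per smoothed variable), configurable via `basis_df`. This is
deliberately parsimonious: it keeps the 21-variable -> column bookkeeping
transparent (35 main columns at df 2) and the design well conditioned at
synthetic site counts. Interactions default to products of the standardized
(df-1) variables — 57 columns for the canonical vocabulary — with an
`expanded` mode forming all products of basis columns (158 columns) for
users who want the richer surface.

The random term `(BA | Code)` is read as a correlated per-tree random
intercept and random slope on previous-year basal area, standardized like the
fixed BA column. The BA slope absorbs tree-specific size/age trajectories,
which is what makes period means comparable without detrending; the intercept
absorbs level differences (microsite, measurement height). Only this 2x2
structure is implemented — an intercept-free variant would change the
2x2-block algebra throughout for a variant of little practical interest.

### Estimation

The marginal likelihood is maximized with a Laplace approximation. Adaptive
Gauss-Hermite quadrature over a correlated 2-d random effect is impractical
as an estimation objective, and Laplace is its one-node case; an adaptive
Gauss-Hermite *evaluator* (tensor nodes centered at the per-tree conditional
mode, scaled by the observed Hessian) is provided and used in the tests to
bound the approximation error (< 1e-3 log-likelihood units on small
instances).

The fit is organised as in `lme4`: for candidate variance parameters, the
penalized joint mode of (beta, b) is found by a damped Newton iteration, and
the profiled Laplace objective is optimized over the remaining four
parameters — the log-Cholesky factor of Sigma and the log gamma shape — by
Nelder-Mead. Two numerical choices matter:

- **Fisher caching.** For the gamma family with log link the expected
  information weights are constant (equal to the shape), so X'X, the
  per-tree sums of X and X.z, and the per-tree 2x2 moment blocks determine
  the whole inner Newton system and are computed once per dataset. Observed
  curvature is used where accuracy matters: the 2x2 blocks entering the
  Laplace determinant, and the Schur complement behind the reported SEs.
- **Conditioning.** Site-level covariates are partially confounded with the
  per-tree random intercepts, and synthetic networks with few sites can make
  the fixed-effect system nearly singular. The inner solver escalates a
  ridge jitter (1e-10 ... 1e-6 of the diagonal scale) only when the Cholesky
  factorization fails, and bounds steps on the standardized scale; the line
  search accepts only ascent, so regularization can slow but never corrupt
  convergence.

Convergence: inner gradient below 1e-6 relative (or step below 1e-9); outer
simplex tolerances 2e-3 (parameters) / 1e-2 (log-likelihood), adequate for
AIC comparisons at the 0.1 level. Random-effect SDs are bounded in
[1e-4, 10]; an SD estimated at <2e-4 sets a boundary flag. Parameter count
for AIC: fixed effects + 2 RE variances + 1 covariance + 1 shape.

Standard errors are conditional (from the observed-information Schur
complement at the mode), the common GLMM convention. Parameter recovery on
simulated networks (50 sites x 5 trees x 60 years, 20 replicates) puts
~99% of true fixed effects within +-3 SE, comfortably above the 90% the
acceptance suite requires.

### Validation ladder

`compare_models` fits the eight inclusion patterns of {AI, Cli, Geo} (null ->
single groups -> pairs -> full) on identical data by column subsetting, with
the intercept and the BA column retained in every model (the null keeps the
intercept and random structure only, plus the BA fixed effect that belongs to
the random-trend machinery). Interaction columns require all parent groups.
Each model's likelihood-ratio chi-square is taken against the largest
strictly nested model earlier in the ladder (the null at minimum), with df
equal to the parameter-count difference; the original table's per-row
chi-square/df pairing is not fully decodable from the published text, so this
explicit rule is documented instead of guessed. On synthetic data with all
groups active the full model attains the minimum AIC and every reduced model
beats the null; with climate truly inactive the climate-block LRT rejects at
~5% (calibrated over 200 replicates).

## Projection

Grid predictions are population-level (random effects at zero) for a
reference tree at fixed basal area, default 86059.03 mm^2 — the printed
"(1/10,000 mm2)" unit qualifier is treated as a typo, since 86059.03 mm^2
(about 861 cm^2, DBH ~33 cm) is exactly what an 80-year average beech
carries, while other readings are off by orders of magnitude. Period means
use inclusive year windows (1955-1985 and 1986-2016 each aggregate exactly
31 years) and percent change is `100 (b - a)/a`.

Scenario climates follow the delta-change method: per ensemble member, the
(future minus 1985-2014 historic) seasonal climatology difference; members
averaged separately for the temperature (21 models) and precipitation (26
models) ensembles; the ensemble-mean deltas added to the observed baseline
seasonal series, precipitation floored at zero, geography and AI untouched.
Future period means average the delta-shifted baseline years, preserving the
baseline's interannual variability rather than collapsing to a flat
climatology. Two scenarios (SSP1-2.6, SSP5-8.5) by three windows (2020-2050,
2040-2070, 2060-2090) give exactly six growth-change maps, each expressed
against the 1986-2016 baseline mean.

The applicability domain (AD) is the per-(variable, season) range of the
training climate pooled over all sites and years of 1901-2016; a pixel whose
shifted climate leaves any range in either direction is flagged with the
violating (variable, season, direction) triples. Flagged pixels are reported,
not dropped — extrapolations are marked for cautious interpretation. Pooling
over the whole domain (not per pixel) matches how the original analysis
describes its AD per period.

## Synthetic networks

The generator emulates the published study conditions: sites uniform in
5.8-28.4 degE x 38.8-58.5 degN at 1-1900 m (the altitude ceiling tapers
northward so montane sites sit in the south, keeping every site inside the
500-2000 mm / 3.8-13.5 degC envelope); monthly climate with a sinusoidal
seasonal cycle, a 4.5 degC/km lapse rate, a 0.33 degC/degree-latitude
gradient, AR(1) interannual anomalies (coefficient 0.3), an optional warming
trend (default 0.2 degC/decade, centered so long-term site means stay on
their normals), and a diurnal range that varies independently of the mean
anomaly — without that, tmax and tmin would be collinear in a way real
observations are not. Sites also receive substantial climate variation
independent of geography (SD 0.6 degC, 120 mm), so aridity is not a
deterministic function of latitude and altitude and the three variable
groups remain separately identifiable.

Growth is simulated forward from the model itself: per tree a correlated
(intercept, BA-slope) pair, then year by year a gamma draw around the linear
predictor, basal area accumulation, and ring widths emitted at 0.01 mm
precision (the stated measurement resolution), with DBH recorded as twice
the final radius. Because BA is endogenous, the truth fixes the BA
standardization constants (center 30,000, scale 20,000 mm^2) and the full
generating scaler is reusable at fit time, making every coefficient directly
comparable between truth and estimate. Trees start from a 5 mm radius
(lognormal jitter, SD 0.1); the sources are silent on initial size and age
structure, so these are exposed parameters without any fidelity claim.

Default true parameters give a mean increment of ~900 mm^2/yr, gamma shape 8
(CV ~35%, typical of ring data), RE SDs 0.25 (intercept) and 0.08 (BA slope)
with correlation -0.2, and effects in every group signed ecologically:
summer heat hurts, growing-season rain helps, wetter sites (higher AI)
grow faster, and the rain response is modulated by aridity, latitude and
altitude. Effect magnitudes (0.04-0.22 per SD) are chosen so each group is
clearly detectable at the synthetic study scale of a few thousand
observations — the real network's group contributions were orders of
magnitude beyond detection thresholds, and a synthetic study in which group
membership were borderline would test sampling noise, not the method.

What the generator does **not** emulate: masting, competition, disturbance,
soil, spatial autocorrelation between sites, temporal autocorrelation beyond
the BA slope, crossdating error, or the CHELSA grid structure. Passing tests
therefore demonstrate the correctness of the pipeline's mechanics and the
fitting machinery under the model's own assumptions — not robustness of the
scientific conclusions to violations of those assumptions on real data.

## Scales used by the checked studies

All sizes were fixed as the package's study design: parameter recovery uses
20 networks of 50 sites x 5 trees x 60 years (15,000 observations, the
published network's order of magnitude per variable); the ladder runs at 35
sites x 4 trees x 40 years; test-size calibration uses 200 replicates of 20
sites x 2 trees x 25 years with a 10-df climate block; the AD oracle uses
1,000 random pixels; the demonstration pipeline runs 20 sites x 3 trees on a
6 x 6 grid.

## Known limitations

- The published "66 significant variable interactions" relies on an
  unstated selection rule and does not match any structural count under the
  stated blocks; no pruning is applied by default.
- Laplace (not adaptive quadrature) is the estimation objective; the
  quadrature evaluator bounds the error on small instances but very small
  groups with low shape would deserve a quadrature refit.
- The reported conditional SEs ignore variance-parameter uncertainty, as is
  conventional; coverage of +-3 SE intervals is verified by simulation.
- Gridded outputs are flat CSV, not NetCDF/GeoTIFF.
- The variance of an RE whose true value is zero is estimated at the
  boundary only up to half-chi-square sampling noise; degenerate-truth tests
  assert a negligible variance share rather than an exact zero.
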