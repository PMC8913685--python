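# beechgrow

Continental-scale modelling of European beech (*Fagus sylvatica*) radial
growth: from raw tree-ring widths to climate-driven growth projections.

The package is aimed at dendroecologists and forest modellers who want to
(1) convert dated ring-width series into annual basal area increments (BAI)
anchored on the sampled stem diameter, (2) fit a continent-wide growth model
from seasonal climate, aridity and geography, (3) validate it by a nested
AIC / likelihood-ratio ladder, and (4) project growth change over space
under delta-shifted CMIP6-style climate scenarios, flagging pixels where the
model would extrapolate. A synthetic-network generator with known ground
truth makes the whole pipeline testable without any restricted data.

## The model

Annual BAI of tree *j* at site *i* in year *t* is modelled as gamma
distributed with a log link:

```
log E[BAI_ijt] = β0 + log(AI_i) + f(LAT_i) + f(ALT_i)
               + Σ_k [ f(Tmax_itk) + f(Tmin_itk) + log(PP_itk) ]
               + log(AI_i)×f(LAT_i) + log(AI_i)×f(ALT_i) + f(LAT_i)×f(ALT_i)
               + {log(AI_i), f(LAT_i), f(ALT_i)} × climate_itk
               + b0_j + b1_j · BA_ijt
BAI_ijt ~ Gamma(shape, mean = E[BAI_ijt]),   (b0_j, b1_j) ~ N(0, Σ)
```

with seasons *k* from previous-year summer to current-year autumn (pSUM,
pAUT, WIN, SPR, SUM, AUT — 21 model variables in all), `f(·)` a quadratic
basis on the standardized variable, AI the De Martonne aridity index
`P/(10+T)`, and a correlated per-tree random intercept and random slope on
previous-year basal area (BA) that absorbs size/age trends so period means
compare without detrending. Fitting maximizes the Laplace-approximated
marginal likelihood (lme4-style penalized inner Newton with the
variance/dispersion parameters profiled by a derivative-free outer
optimizer); an adaptive Gauss–Hermite evaluator cross-checks the
approximation. See `docs/methods.md` for assumptions, numerics and
limitations.

## Worked example

```python
import beechgrow as bg

# synthetic 20-site network grown from known parameters
net = bg.generate_network(n_sites=20, trees_per_site=3, year_range=(1957, 2016), seed=1)
bai = bg.network_bai_table(net.rings)                 # widths+DBH -> BAI, mm^2/yr
seasonal = bg.aggregate_seasons(net.climate)          # monthly -> 6 seasons
design = bg.build_design(bai, seasonal, net.sites, bg.ModelSpec())
fit = bg.fit_glmm(design)

members = bg.generate_scenario_ensemble(net.sites, seed=2)
deltas = {k: bg.ensemble_mean_delta(t, p) for k, (t, p) in members.items()}
results = bg.run_scenarios(fit, seasonal, net.sites, deltas, training_seasonal=seasonal)
```

prints (via the obvious formatting calls):

```
n_obs=3600  trees=60  loglik=-25774.1  AIC=51744.1
gamma shape=8.18  RE sd(intercept)=0.239  RE sd(BA)=0.083
  (Intercept)  +6.800 +- 0.032   (truth +6.802)
  ai           +0.200 +- 0.083   (truth +0.220)
  pp_SUM       +0.120 +- 0.011   (truth +0.120)
  tmax_SUM^1   -0.122 +- 0.034   (truth -0.100)
SSP1-2.6  (2020, 2050): median   -5.6%  range [ -36.9,   +6.4]  inside AD 90%
SSP1-2.6  (2040, 2070): median   -6.2%  range [ -47.2,   +7.9]  inside AD 90%
SSP1-2.6  (2060, 2090): median   -7.2%  range [ -49.7,   +9.6]  inside AD 90%
SSP5-8.5  (2020, 2050): median  -10.1%  range [ -56.2,  +10.1]  inside AD 90%
SSP5-8.5  (2040, 2070): median  -16.9%  range [ -74.7,  +12.6]  inside AD 85%
SSP5-8.5  (2060, 2090): median  -28.7%  range [ -86.7,  +10.9]  inside AD 75%
```

Reading this: the fitted intercept, summer-rain and summer-heat coefficients
recover the generating truth within a standard error or two; the gamma shape
8.18 corresponds to a ~35% coefficient of variation of annual increments.
Each scenario line is one growth-change map for a reference tree at fixed
basal area (86059.03 mm², an ~80-year beech): median percent change of
31-year mean BAI relative to the 1986–2016 baseline across grid pixels, its
spatial range (southern/low-elevation pixels lose most, the far north
gains), and the fraction of pixels still inside the model's applicability
domain — which shrinks as the late-century high-emission climate leaves the
training range.

The same pipeline is scriptable from the shell:

```
beechgrow run --seed 1 --outdir out/       # simulate -> bai -> fit -> ladder -> project
beechgrow report --outdir out/             # latitude-band summary
```

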