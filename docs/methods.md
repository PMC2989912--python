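# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `fruitscape`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and time conventions

Positions are projected meters, y increasing north; observation windows are
arbitrary simple polygons (WKT/GeoJSON), with a rectangular default for
tests. The season clock starts at July 1 (day 0) and runs 365 days; seasons
are indexed by the July 1 that opens them. DBH is in millimeters.

## Spatial point process

**Model.** Homogeneous Poisson as the reference (λ̂ = n/|A|, the closed-form
MLE), and an inhomogeneous Poisson process with log-linear intensity
log λ(s) = α + β·Z(s). The link is a modeling choice — the log-linear form
is the standard covariate formulation and guarantees λ > 0; a proportional
option (λ = β·Z) exists behind the `link="proportional"` flag for
sensitivity analysis.

**Covariate.** Z is the isotropic Gaussian kernel density of aerially
detected trees, evaluated exactly at raster cell centers (no binning), with
optional edge correction that renormalizes each point's kernel by its mass
inside the window so the surface integrates to the total weight. Detected
points may be inverse-probability weighted (w = 1/p̂(detect|DBH)) so the
surface estimates *total* density; an unweighted mode exists because only
relative intensity matters for the process fit. Covariate values off the
grid come from bilinear interpolation between cell centers, lower-left cell
convention on edges.

**Estimation.** Berman–Turner quadrature: data points plus masked cell
centers as nodes, node weight = cell area / nodes-in-cell, fit as a weighted
Poisson GLM (statsmodels). At the MLE the quadrature expectation of the
count equals the observed n (score identity; verified to 1e-6 relative).

**Bandwidth selection.** The smoothing bandwidth is chosen on a user grid
(default 50–400 m) by maximizing a leave-one-out cross-validated process
log-likelihood: the covariate value at each fitted point excludes that
point's own kernel contribution (in grid-interpolated form, consistent with
the quadrature). Without the LOO correction the criterion degenerates to
σ → 0 whenever the fitted pattern contains the detected points. Recovery
tests show the criterion selects the generating bandwidth's neighborhood on
the default grid.

**Simulation.** Thinning: propose homogeneous Poisson at λ_max over the
bounding box, retain with probability λ(s)/λ_max (0 outside the window).
Counts are exactly Poisson(∫λ).

**Goodness of fit.** qq-type envelope of smoothed raw residuals: the
observed kernel-smoothed intensity minus the smoothed fitted intensity on
the raster (smoothing default: 5% of the window extent; mask-normalized),
reduced to quantiles and compared with n_sim simulations from the fit. The
critical band is *simultaneous*: the scaled-maximum-deviation (global)
envelope calibrated on the simulated curves, so whole-curve coverage is the
nominal 95% by exchangeability; a pointwise band would be inside-everywhere
far less than 95% of the time and would make the diagnostic reject correct
models too often. With n_sim = 39 the self-consistency rate is ~95%
(measured ≥ 90% over 50 replicates in the acceptance suite).

## Detectability

Logistic GLM of aerial visibility on DBH. When labeled data are unavailable
the intercept is calibrated by 1-D root finding (Brent, tolerance 1e-8 on
the fraction) so the mean detection probability over a DBH sample matches a
stated overall fraction; the slope is then a configuration input (default
0.003 per mm). Calibration averages only over stems above 200 mm DBH by
default, because overall visibility fractions are reported for canopy-sized
trees. Perfect separation is detected and raised as an explicit error
rather than returning a divergent fit.

## DBH distribution

Rank transformation to normality: sorted reference DBHs are paired with
normal scores Φ⁻¹((rank − 0.5)/n), midranks for ties. Sampling draws
z ~ N(0,1) and inverts the map by linear interpolation in (score, dbh)
space; beyond the reference range the terminal segment is extrapolated
linearly and clamped to [0.9·min, 1.1·max], preventing absurd giant stems.
The back-transform interpolation rule is our choice; at n = 10⁴ the sampled
distribution matches the reference CDF within KS distance 0.02.

## Phenology

**Metrics.** Per tree-season: production = Σ counts; peak = count-weighted
mean day; duration = 4 × count-weighted SD of days with the n−1 denominator
over individual fruits (all fruits of a weekly visit carry the visit day).
Peak needs ≥ 1 fruit, duration ≥ 2; undefined metrics are emitted as
missing, never silently zero.

**Model II (fruit dates).** day = c₃ + w_i + z_j + ε with independent
crossed normal intercepts, fit by REML. The deviance is profiled lme4-style
from the q×q random-effect cross-product system (q = trees + seasons), so
cost is independent of the number of fruits once cross-products are formed;
the implementation agrees with R lme4 to ~1e-4 on a frozen reference
dataset (see tests). Designs with one observation per tree-season cell
cannot separate the residual variance and raise a non-identifiability error.

**Model I (season totals).** N_ij ~ Poisson(exp(c₁ + c₂·dbh_i + u_i + v_j)),
fit by maximizing the Laplace approximation over the stacked random-effect
vector: inner damped Newton for the joint mode (penalized-score ∞-norm
< 1e-8), outer L-BFGS-B over (β, log sd) with fixed-effect columns
standardized internally for conditioning. Standard errors come from the
numerical observed information in (β, log sd), delta-mapped to the reported
scales. Agrees with lme4's `glmer` (Laplace) to ~1e-3 on a frozen reference
dataset.

**Descriptive fits.** The three per-metric models (production / peak /
duration) reuse the same machinery: Gaussian REML for peak and duration
(intercept-only fixed part), and the production model *is* model I.

**Bootstrap p-values.** Variance components sit on the boundary under the
null, so p-values come from a parametric bootstrap of the LR statistic:
simulate n_boot datasets from the fitted null (component removed), refit
both models, p = (1 + #{LR* ≥ LR_obs})/(n_boot + 1). For Gaussian models
the refits use a grid-profiled REML deviance (fixed, data-independent grid
of relative SDs; the theta-factorization is shared across the whole
bootstrap batch) — the same estimator is applied to the observed statistic,
which preserves exchangeability; measured type-I error at nominal 5% is
0.045 over 200 replicates. Fixed-effect tests use ML likelihoods. Poisson
GLMM bootstraps refit per dataset (slower); failed refits are discarded and
more than 10% failures raise.

## Synthetic data

The generator emulates the study conditions end to end: a smooth covariate
(kernel-smoothed coarse random point set, standardized), an inhomogeneous
Poisson census with DBH-dependent Bernoulli visibility, and trap records
with Poisson totals and normal fruit dates, with optional 7-day binning to
mimic weekly trap visits. Defaults are the documented parameter set; the
reference DBH pool is lognormal (median 650 mm, log-SD 0.45, clipped to
[210, 2200] mm), our choice of a realistic size distribution for
reproductive canopy emergents above the 200-mm visibility threshold.
`fruits_scale` multiplies expected totals so recovery experiments can be
well conditioned relative to the sparse (≈10³ fruits) field reality; the
unscaled mode exists for realism tests. What the generator does *not*
emulate: spatial correlation between phenology and location, trap-level
sampling of crowns, non-Gaussian season shapes, year-to-year trends — so
green recovery tests certify the estimators, not the biology of real data.

## Recovery experiment designs

Problem sizes are chosen so every parameter is well identified while the
full suite stays quick: model II uses 150 trees × 30 seasons × ~30 fruits
per cell (~1.6·10⁵ fruits); model I uses the same crossed design at unit
scale with DBH uniform on 500–1500 mm; detection calibration simulates 10⁵
stems; spatial recovery and envelope self-consistency use 50 replicates of
~10³-point patterns; the bootstrap calibration study uses a 15 × 10 × 5
design with n_boot = 199 and 200 outer replicates. Estimated SDs of
tree/season effects track the *realized* draw of those effects, so at 30
seasons a season-level SD estimate has an inherent ~13% sampling spread —
the 15% recovery tolerance reflects that, not estimator bias.

## Simulator

Expected curves are evaluated on a daily grid over the 365-day season and
are not renormalized for truncation (mass outside ±6σ of the peak is
< 1e-4 at the default parameters). Realized counts are independent Poisson
draws per (tree, season, day-bin) with mean λ_ij(t)·Δt. u, v, w, z are
drawn independently — no production-peak correlation is modeled. λ is
calibrated to *trapped* fruits; `trap_to_tree` multiplies to whole-tree
production if the user supplies a conversion.

## Known limitations

* No interaction (Gibbs) or cluster point processes: the intensity model
  explains aggregation only through the covariate.
* The nonlinear Gaussian-curve Poisson mixed model (one curve per
  tree-season) is deliberately not implemented; the two-model decomposition
  replaces it.
* Aerial imagery itself (georeferencing, crown identification) is out of
  scope; visibility enters only as labels or a calibrated fraction.
* GeoTIFF export is not provided; surfaces persist as ESRI ASCII grids.
* The Laplace approximation can bias variance components at very low counts
  (< 1 fruit per cell on average); recovery at the default designs shows no
  material bias, but sparser designs deserve the bootstrap.
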