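# Methods

This note documents the statistical model, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, and
the numerical decisions inside the implementation.

## The estimation problem

Net-tow stations measure areal concentration of floating plastic (pieces
km⁻²) at scattered points in space and time. Three features make a naive
annual mean useless as a global trend:

1. **Censoring.** A tow that catches nothing says only that the local
   concentration was below `1/a` for swept area `a`. Zero catches are
   common and their "detection limit" varies per station.
2. **Wind.** Buoyant particles are mixed below the sampled few tens of
   centimetres when the wind blows, biasing raw tows low by a
   wind-dependent factor.
3. **Spatial sampling bias.** Effort concentrates in the North Atlantic
   and North Pacific, and inside gyres; a year's mean is confounded with
   where ships happened to sample.

The pipeline addresses each in turn and then reads the time trend from
spatially-debiased residuals rather than from a joint spatio-temporal
model, which the uneven record could not support.

## Wind-mixing correction

The vertical distribution of rising particles in a wind-mixed surface layer
is exponential with depth scale `A₀ = 1.5·u*_w·κ·H_s`. The fraction of the
column visible to a net immersed to depth `d` is `1 − exp(−d·w_b/A₀)`, so
observed concentrations are multiplied by its inverse. Parameters, with
defaults:

| parameter | default | units | role |
|---|---|---|---|
| `rise_velocity_wb` | 0.02 | m s⁻¹ | particle rise velocity |
| `net_immersion_depth_d` | 0.25 | m | half a 0.5 m aperture |
| `von_karman_kappa` | 0.4 | – | boundary-layer constant |
| `drag_coefficient_cd` | 1.2×10⁻³ | – | 10 m neutral drag |
| `air_density` / `water_density` | 1.22 / 1025 | kg m⁻³ | friction-velocity transfer |
| `wave_height_coefficient` | 0.0214 | m⁻¹ s² | `H_s = c·U10²` (fully developed sea) |
| `max_factor_cap` | 10 | – | storm-wind guard |

Only wind speed is available per station, so `H_s` comes from the
fully-developed-sea relation rather than measured wave height. The rise
velocity default (0.02 m s⁻¹, within the standard range for millimetre-
scale buoyant fragments) is calibrated so that the *average* correction
under a moderate open-ocean wind climate (Rayleigh-distributed `U10` with a
6 m s⁻¹ scale) is ≈2.5–2.9×, the magnitude reported for neuston-tow
corrections of this kind; slower rise velocities push the average correction
above 4×. The cap prevents a handful of storm stations from dominating the
fit; cap hits are counted in the table attributes. Censored records have
their detection limits scaled by the same factor as data, keeping the
censoring threshold consistent on the corrected scale.

## Censored imputation (ROS)

Zeros are treated as left-censored lognormal observations. Because the
detection limit is `1/a` and swept areas vary, the implementation uses
Hirsch–Stedinger plotting positions, which handle multiple censoring
thresholds: exceedance probabilities of the ordered limits are built
recursively from the largest down, detected values get Weibull-type
positions within their inter-limit interval, and censored values get
positions spread below their own limit. Ordinary least squares of
`log(value)` on the standard-normal quantiles of the detected positions
then predicts each censored element at its own position. Imputed values
are clipped at their detection limit (clips are counted); detected values
are never touched, so imputation preserves their ranks. The procedure is
deterministic; the model is fitted globally by default (`--group-by basin`
exists as a sensitivity option, since the pooling level is a genuinely open
choice). Preconditions: at least 3 detected values and a censored fraction
of at most 0.8.

## Spatial reference

Six basins (North/South Atlantic, North/South Pacific, Indian,
Mediterranean) partition the ocean. The packaged boundaries are deliberately
simple — the equator splits the Atlantic and Pacific, 20°E separates
Atlantic from Indian, 147°E Indian from Pacific (100°E north of the
equator), a Central-American diagonal separates Atlantic from Pacific, and
the Mediterranean is a priority box — and ship as an editable GeoJSON file.
Stations in enclosed seas outside the partition fall back to the nearest
basin, with a log entry.

The expected-concentration field is any 1° grid of relative concentration
(long CSV `lat,lon,value`). It is z-scored within each basin (sample SD,
ddof = 1) so that the stage-1 covariate means "relative to its basin", and
a basin that is constant or has fewer than two ocean cells is rejected as
degenerate. Lookup is piecewise constant per cell with a nearest-ocean-cell
fallback within 2°. The packaged synthetic field (subtropical-gyre Gaussian
maxima over a smooth random background, no land) is a clearly labeled
non-physical stand-in used by the tests and simulations; any user-supplied
modeled field with the same interface replaces it.

## Two-stage trend model

**Stage 1** fits `log C = β₀ + s(z) + basin + ε` by a penalized Gaussian
additive model. The response is log concentration: concentrations are
approximately lognormal, and after the log transform a Gaussian likelihood
is the coherent choice (a gamma likelihood cannot be applied to logged
data, which may be negative; a gamma-with-log-link fit on the raw scale is
provided as a sensitivity option via statsmodels and yields near-identical
residuals on synthetic data). With only one basin represented the basin
term is dropped with a warning. Residuals are taken on the log scale.

**Stage 2** fits a penalized cubic B-spline smooth of those residuals on
continuous time (days since 1979-01-01, scaled to years), basis dimension
20 over the 41-year window, second-difference penalty, smoothing parameter
by restricted maximum likelihood (GCV available). The fit and its pointwise
standard errors are evaluated on a daily calendar grid (leap days
included). Where a year has no stations, the spline's own extrapolation
variance widens the band — visibly so before 1990 and after 2015.

**Globalization.** The back-transformed trend is anchored so that
`exp(r(t) − a)` averages to exactly 1 over the observed station times
(`a = log mean exp(r(t_i))`). Without the anchor, multiplying the observed
mean concentration by `exp(r(t))` overstates the level by the ratio of the
arithmetic to the geometric mean of the trend over the sampling times —
about 8–12 % under a realistic trend shape — because the residual smooth is
centered in log space while the observed mean is arithmetic. Daily global
count is `C̄·exp(r(t) − a)·A_ocean` with `A_ocean = 361 900 000 km²`;
annual values are simple means of daily values; mass is exactly
count × 1.36×10⁻² g (one fixed mean particle mass — a known simplification;
rounding only at report time).

**Confidence bands** are multiplicative: `exp(r ± 2·SE_tot)` with
`SE_tot² = SE_trend(t)² + SE_anchor²`, where `SE_anchor` is the delta-method
log-scale standard error of the mean concentration `C̄`. The anchor term
matters: station concentrations are heavy-tailed lognormals, so `C̄` alone
carries several percent of sampling error — comparable to the trend SE in
densely sampled years — and a band conditioned on `C̄` under-covers the
truth in simulation (≈65–70 % instead of the nominal ≈95 %). With the
combined band, coverage of the generator's truth is ≈90–95 % across
replicate campaigns. The bands remain symmetric in log space and therefore
asymmetric on the count scale, matching the shape of the reported annual
table.

**Mean concentration** defaults to the arithmetic station mean; a
basin-area-weighted alternative is available for strongly unbalanced
campaigns.

A single combined model `log C ~ s(z) + basin + s(t)` (two penalties,
joint REML) is implemented as a cross-check; on synthetic campaigns its
centered annual trend stays within the two-stage model's 2 SE band in
well over 90 % of years. The two-stage decomposition is preferred because
it keeps the time effect interpretable under space–time collinearity.

## Synthetic campaigns

The generator draws, per station: a grid cell (cos-latitude weighted within
its basin) with its field z-value; true concentration
`exp(μ_b + 1.0·z + N(0, 1.2²))·m(t)`; wind `U10 ~ Rayleigh(6 m s⁻¹)`; an
*observable* concentration equal to the true one divided by the same mixing
factor the pipeline later applies; tow geometry (width ∈ {0.5, 0.6, 1.0} m,
lognormal distance, median 1 km); a Poisson catch over the swept area —
which produces true zero catches (≈8 % at the defaults); and a mesh size
drawn from {53, 200, 333, 505} µm with shares {0.2, 2.5, 94.8, 2.5} %.
Effort follows a fixed 41-year profile (a handful of 1980s stations, dense
1990–2015 coverage, little after) split 33/34/6/9/10/8 % across
NA/NP/SA/SP/Indian/Mediterranean — about 4 700 stations per campaign. The
default trend `m(t)` is piecewise log-linear: mild rise to the mid-1990s, a
dip to ≈0.55× around 2004, then growth to ≈2.5× by 2019.

Basin log-means (10.2–10.4 log pieces km⁻²; Mediterranean highest) are set
so the station-weighted and area-weighted global means agree to within
≈1 %: the default campaign is unbalanced in *effort* but approximately
representative in *level*. That is a deliberate assumption — the estimator
anchors the global level to the observed mean, so a campaign whose heavily
sampled basins are systematically richer or poorer than the ocean average
would bias the level by the same factor, and no within-method correction
exists short of area-weighting the mean (the provided option). Passing
recovery tests therefore demonstrates trend-shape and level recovery under
representative-in-level sampling, not robustness to level-biased sampling.

Also deliberately *not* emulated: spatial autocorrelation beyond the shared
expected field, seasonal cycles, particle-size spectra, and any real ocean
circulation. The per-group child generators (one per year × basin) make
campaigns differing in a single knob pairwise comparable and the whole
table byte-reproducible for a given seed.

Closed-form truth: the annual global count implied by a configuration is
computed from the field grid (per-basin mean of `exp(z)`, cos-latitude
area weights, lognormal mean factor `exp(σ²/2)`, daily mean of `m(t)`),
giving the target for recovery tests without simulation error.

## Numerical choices

- Penalized fits solve `(X'X + Σλ_jS_j)β = X'y` by Cholesky; a vanishing
  ridge (10⁻¹²–10⁻⁶ of the mean diagonal, escalated only on failure)
  guards basis columns with no data support at very small λ.
- REML: profiled criterion
  `(n−M)/2·log(RSS+λβ'Sβ) + ½log|A| − ½(r·logλ + log|S|₊)`, minimized by a
  31-point log-grid plus bounded refinement (one smooth) or a coarse grid
  plus Nelder–Mead (several smooths). Deterministic throughout.
- Smooth bases are column-centered against the training data so the model
  intercept stays identifiable; prediction rows reuse the stored offsets,
  and covariates are clipped to the training range (flat extrapolation of
  the basis beyond it).
- A basis requested with more functions than distinct covariate values is
  shrunk with a warning.
- The residual variance is floored at 10⁻²⁴ so standard errors stay
  strictly positive even on degenerate (exactly constant) inputs.
- Stage-2 problem size: 41 years daily ≈ 15 000 grid rows × ≈21
  coefficients — small enough that the full pipeline runs in ≈1 s for a
  4 700-station campaign, and the 20-replicate recovery study in ≈10 s.

## Known limitations

- One mean particle mass converts counts to mass; real mass per particle
  varies by orders of magnitude with size class.
- The expected field is static; any secular change in the spatial pattern
  is absorbed into the residual trend.
- Basin boundaries are schematic; marginal-sea stations are assigned to
  the nearest basin rather than excluded.
- The confidence band propagates trend and level-anchor uncertainty but
  not wind-parameter or imputation-model uncertainty.
- Years with zero stations are pure spline interpolation/extrapolation;
  their point estimates inherit the smoothness assumption and should be
  read through their (wide) bands.
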