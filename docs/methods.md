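# Methods

This note documents the models and numerical choices behind `conipheno`,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Camera color indices and composites

Indices are computed **per image** and then aggregated — not the other way
around — because quantile statistics do not commute with the ratio forms of
Gcc and GRVI. Quantiles use linear interpolation between order statistics
(numpy's default, the "type 7" convention), fixed so composites are
bit-reproducible. Three-day windows are anchored at day-of-year 1 (days
1–3, 4–6, …) and the composite carries the window's middle date, which
bounds any phase error at one day. Snow handling consumes an explicit
per-image snow flag; the package trusts the flag rather than re-detecting
snow (an optional brightness/GRVI heuristic was considered and rejected as
a default because a misfiring heuristic silently biases winter baselines).

The seasonal signal-to-noise ratio is the amplitude of the LOESS-smoothed
series divided by the mean absolute day-to-day difference of the raw
retained series. Sites are screened at SNR ≥ 20:1 before model fitting;
the default synthetic site sits near 13:1 on raw daily observations and
above the screen after multi-image compositing.

## LOESS smoother

`loess_smooth` is a locally weighted **quadratic** regression with tricube
distance weights and optional bisquare robustness iterations (two by
default). It is written in-house because no installed library provides
quadratic LOESS with robustness *and* pointwise intervals. Numerical
details that matter:

* **Span.** The default span targets 0.3 of one seasonal cycle's points:
  for an n-year series, span = 0.3/n. A fixed fraction of the whole series
  would widen the window with record length and systematically flatten the
  spring rise (we measured ~9-day SOS bias on a 2-year capacity series
  before adopting the per-year rule).
* **Windows.** For sorted abscissae the k-nearest neighborhood is
  contiguous, found by a two-pointer sweep; all local fits are solved as a
  batched 3×3 system with a 1e-12 ridge to guard duplicate-date windows.
* **Robustness floor.** When the local fits reproduce the data to float
  precision, the residual MAD is ~1e-17 but nonzero; naive bisquare
  weighting would then zero out nearly every point. A MAD below
  1e-9 × SD(y) disables reweighting. The same floor applies in
  `detect_outliers`, whose default threshold is 4×MAD; note that on pure
  Gaussian residuals a 4×MAD rule flags ~1% of points by chance, so exact
  no-false-positive checks are only meaningful at larger k.
* **Intervals.** Pointwise 95% bands come from the hat-vector norm of each
  local fit times a global robust residual variance.

## Transition dates

Crossing days interpolate linearly between the last sample below and the
first at/above the threshold level. A crossing must hold for five
consecutive samples (configurable) to count, which guards against
noise-induced early dates. Rising crossings are searched up to the annual
peak, falling crossings after it; seasons are evaluated per calendar year
(all intended sites are Northern Hemisphere). The amplitude baseline
(min + f·(max−min)) is per-year by default; a whole-record mode exists.
Bootstrap intervals resample residuals about the smooth i.i.d., re-smooth,
and re-extract; dates absent in more than half the replicates are reported
without an interval and flagged. Residual (not block) bootstrap is the
simplest scheme consistent with per-day exchangeable noise; serially
correlated residuals would make these intervals anti-conservative.

## Flux processing

Nighttime is PPFD < 5 µmol m⁻² s⁻¹. The automatic u* threshold bins
nighttime records into 20 u* quantile bins and takes the first bin whose
mean NEE reaches 95% of the top-three-bin plateau — a change-point
simplification adequate for screening, not a replacement for full
bootstrap MPT methods. Gap-filling is a similarity look-up table (same
hour ± 7 days, PPFD within ±200, temperature within ±2.5 °C, doubling all
three until ≥ 3 donors, at most three doublings); it is deliberately
simpler than the full marginal-distribution-sampling hierarchy of
dedicated flux tools and is validated hold-one-out against generator
truth.

Partitioning uses GPP = Reco − NEE under the micrometeorological sign
convention (NEE < 0 is uptake), which keeps GPP ≥ 0; negative partitioned
values are floored at zero and counted. Reco for a day is the mean of
retained nighttime NEE over the centered 5-day window. Because nights are
cooler than days, this nighttime-mean Reco underestimates the
temperature-weighted daily respiration somewhat; this biases GPP levels
but hardly moves threshold-crossing *dates*, which is what the analysis
consumes.

Light-response fits bound Amax ∈ [0, 100] and Km ∈ [1, 5000]
µmol m⁻² s⁻¹ and start from three initial points, keeping the best
converged sum of squares — Michaelis–Menten fits are ill-conditioned when
light never saturates, and multistart plus bounds is the standard remedy.
Windows with under 20 daytime observations or under 50 µmol m⁻² s⁻¹ of
PPFD spread are flagged non-converged and excluded downstream. Years whose
smoothed capacity minimum exceeds 20% of the annual maximum are flagged
non-dormant: threshold dates are still computed but should not be
interpreted as photosynthetic onset/cessation.

## Greenness state-space model

The latent state is deterministic given parameters and weather (all
stochasticity is observation noise), so the posterior is over eight scalar
parameters. The state carries across calendar years without reset, and the
switch day D is sampled continuously and floored when compared to integer
days of year. Snow-flagged and missing days are excluded from the
likelihood while the state still advances — state-space semantics, not
data deletion. The initial state is γ_min when the record starts before
day-of-year 60 (winter dormancy), otherwise the first observation clamped
to the bounds.

Priors are weakly informative: θ₁, θ₂ ~ N(0 °C, 10 °C);
ρ₁, ρ₂ ~ Half-N(0.01); D ~ U(152, 274) (June 1 – Oct 1);
γ_min ~ U(0.2, q10 + 0.01), γ_max ~ U(q90 − 0.01, 0.6) where q10/q90 are
observed quantiles; σ² ~ Inv-Gamma(2, 1e-5). The ±0.01 margin on the bound
priors matters: the observed 10th percentile lies *below* the true winter
baseline whenever observation noise exists, so anchoring the prior support
exactly at the quantile excludes the truth and forces an outward bias in
both bounds (and a compensating inflation of σ) — we measured exactly this
failure before adding the margin.

Sampling is Metropolis-within-Gibbs: Gaussian random-walk updates for the
seven structural parameters with Robbins–Monro scale adaptation toward a
0.44 acceptance rate during warmup only (frozen afterwards, preserving
detailed balance for retained draws), and a conjugate inverse-gamma draw
for σ² given the trajectory residuals. Defaults are 4 chains ×
(5000 warmup + 5000 kept) iterations; the tests and acceptance script use
2 chains × (1500–2500 + same), which this 8-parameter posterior mixes
through in a few seconds thanks to a compiled state recursion. Split-R̂
and bulk ESS come from arviz; R̂ > 1.1 on any parameter flags (but does
not discard) the fit. The thresholds θ and sensitivities ρ mix slowest
(they are strongly correlated through the spring sum); medians are stable
well before R̂ reaches 1.01.

**Identifiability.** D is structurally weakly identified: between the last
spring-like day and the first autumn night below θ₂, moving D changes
nothing observable, so its posterior spans roughly [prior lower bound,
first cold night] and its credible interval over-covers. The flat-data
check (posterior ≈ prior overlap > 0.8) verifies the sampler does not
manufacture information. With no reversal mechanism, an unusually warm
midwinter day before D can raise greenness; the recursion implements the
increment rule literally, and no suppression of winter increments is
applied.

Cross-validation fits on years 1..n−1, simulates the whole record with
posterior-median parameters, and scores the final year: R² and RMSE of
predicted vs observed greenness, and predicted vs observed 50%-amplitude
transition dates (the observed dates come from LOESS smoothing of the
held-out year alone).

## Spectral screening

The all-pairs correlation map is fully vectorized over a (dates ×
wavelengths) matrix; cells with constant NDI are masked, and ties in
`best_bands` break to the smallest λ₁ then λ₂. On noise-free constructed
spectra, many weak-amplitude pairs correlate perfectly with the trait by
construction (any monotone deterministic function of the trait does), so
band recovery is only meaningful with observation noise — the tests and
acceptance script add reflectance noise of 0.002 before screening. Camera
simulation integrates response × reflectance by the trapezoid rule with a
common gain and clips to [0, 255]; the bundled response curves are
synthetic Gaussians shaped like consumer-camera channel sensitivities.

## Synthetic-data generator

The generator's defaults describe one cold-continental, winter-dormant
conifer site: annual mean 2 °C, seasonal half-amplitude 14 °C, diurnal
range 10 °C, AR(1) anomalies (φ = 0.7, stationary SD 3 °C), and
interannual offsets of SD 0.8 °C — values typical of the boreal/subalpine
sites where color-based and flux-based phenology agree. Greenness truth
uses θ₁ = 5 °C, θ₂ = 0 °C, ρ₁ = 0.002, ρ₂ = 0.003 per °C·day, D = 200,
γ ∈ [0.36, 0.42], σ = 0.003. Snow can occur on days with Tmax < 2 °C
(probability 0.15), rendered as a convex blend of the scene toward white —
which pulls Gcc toward 1/3, the documented downward snow artifact for
green canopies. Camera records invert Gcc exactly at zero illumination
noise; per-channel noise is Gaussian in DN space. Fluxes couple to the
*latent* greenness via a linear map from normalized γ to Amax (zero at
dormancy), the simplest coupling consistent with the observed
Gcc–capacity concordance; respiration is Q10 in air temperature; PPFD is
a truncated sine scaled by a solar-declination day length (latitude 45° by
default). Each substream (weather, greenness, camera, flux, spectra) draws
from an independent child of the site seed, so fixed seeds give
byte-identical outputs.

What the generator does **not** emulate: cloud fields and aerosol
illumination drift, canopy structure and shadows, storage fluxes and
advection, u*-dependent NEE suppression (u* is drawn independently of NEE,
so the auto-threshold's change-point recovery is tested on separately
constructed data), radiative-transfer realism in the spectra (features are
stylized Gaussians; the synthetic PRI is positive where field PRI is
typically negative), and Southern Hemisphere seasonality. Passing tests
therefore demonstrate the correctness of the algorithms under the stated
statistical structure, not robustness to every field artifact.

## Problem sizes

The test suite and acceptance script use 5-year daily series for model
fitting (≈ 1700 observations), 24 replicate fits for parameter-recovery
and pooled credible-interval coverage, 20 replicate cross-validations,
8 coupled site-years of half-hourly fluxes (≈ 140k records) for the
camera-vs-capacity comparison, and 72 spectra on a 1 nm grid for band
screening. These sizes give stable statistics while keeping a full run in
minutes on a single core.
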