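# conipheno

Canopy-color phenology of temperate evergreen conifer forests: a tested,
reusable pipeline linking digital-camera greenness indices, eddy-covariance
photosynthetic capacity, and a temperature-driven Bayesian model of the
seasonal greenness cycle.

Evergreen conifers keep their needles year-round, yet their canopies change
color with the seasons as pigment pools shift between light harvesting
(chlorophyll) and photoprotection (carotenoids and the xanthophyll cycle).
At winter-dormant sites this color cycle tracks the seasonal onset and
cessation of photosynthesis, so inexpensive cameras can stand in for flux
towers when estimating photosynthetic phenology. This package implements
each step of that analysis and a coupled synthetic-data generator so every
stage runs — and is tested — without downloading any archive data.

## What it computes

**Camera indices** (`conipheno.indices`). Per-image region-of-interest
means of the 8-bit RGB digital numbers are reduced to the green chromatic
coordinate and green-red vegetation index,

    Gcc  = G_DN / (R_DN + G_DN + B_DN)
    GRVI = (G_DN - R_DN) / (G_DN + R_DN)

after excluding images with sun < 5° above the horizon and snow-flagged
days. Indices are aggregated to 1- or 3-day composites by a chosen
statistic (mean, median, 75th or 90th percentile), and a seasonal
signal-to-noise ratio screens sites for model fitting.

**Transition dates** (`conipheno.phenology`). A robust locally weighted
quadratic (LOESS) smoother with outlier rejection; start/end-of-season
dates (SOS/EOS) as the days the smoothed series crosses 10/25/50% of its
seasonal amplitude, with residual-bootstrap confidence intervals;
standardized major axis (Type II) regression and agreement statistics
between any two sets of dates; and the full 12-combination
(statistic × threshold) method grid with aggregate-correlation ranking.

**Photosynthetic capacity** (`conipheno.flux`). Half-hourly NEE is
u*-screened, gap-filled by a similarity look-up table, partitioned with
ecosystem respiration from nighttime NEE in a moving 5-day window
(GPP = Reco − NEE, micromet sign convention), and fit per 5-day window to
the Michaelis–Menten light response

    GPP = Amax · PPFD / (Km + PPFD)

whose value at full sun (PPFD = 2000 µmol m⁻² s⁻¹) is the capacity index
GPPsat. SOS/EOS follow from smoothed GPPsat at fractions of its annual
maximum.

**Greenness model** (`conipheno.model`). A state-space model in which daily
greenness increments follow warmth above a spring threshold before a
switch day D and cold below an autumn threshold after it,

    Gcc_t ~ N(γ_t, σ²)
    γ_t   = clip(γ_{t−1} + Δγ_t, γ_min, γ_max)
    Δγ_t  = max(Tmax_t − θ₁, 0)·ρ₁   (t < D)
          = min(Tmin_t − θ₂, 0)·ρ₂   (t ≥ D)

fitted by Metropolis-within-Gibbs MCMC (conjugate σ² update), with
leave-last-year-out cross-validation and model-derived transition dates.

**Spectral screening** (`conipheno.spectra`). Normalized difference indices
NDI(λ₁, λ₂) = (ρ_λ1 − ρ_λ2)/(ρ_λ1 + ρ_λ2) for every band pair of 400–900 nm
reflectance spectra, correlated against pigment traits (e.g. the chl:car
ratio) to map which band pairs carry the pigment signal; plus broadband
camera simulation by integrating spectra against channel response curves.

**Synthetic data** (`conipheno.synth`). One seed generates coupled weather
(seasonal sinusoid + AR(1) anomalies, boreal defaults), a latent greenness
trajectory from the model above, camera images that invert exactly to the
target Gcc, fluxes whose Amax scales with the latent greenness, and
pigment-driven spectra — each with its ground truth for recovery tests.

## Worked example

`python examples/04_greenness_model.py` fits the model to five years of
synthetic observations (amplitude 0.06 Gcc units, observation noise 0.003)
and validates on the held-out final year:

```
posterior summary (truth in brackets):
  theta1        4.8027  [5.0000]  95% CI (4.4683, 5.1274)  Rhat 1.16
  theta2        0.0595  [0.0000]  95% CI (-0.1348, 0.3229)  Rhat 1.03
  rho1          0.0018  [0.0020]  95% CI (0.0015, 0.0022)  Rhat 1.15
  rho2          0.0029  [0.0030]  95% CI (0.0025, 0.0032)  Rhat 1.02
  d_switch    206.3991  [200.0000]  95% CI (154.3594, 256.8056)  Rhat 1.00
  gamma_min     0.3598  [0.3600]  95% CI (0.3596, 0.3601)  Rhat 1.01
  gamma_max     0.4201  [0.4200]  95% CI (0.4199, 0.4203)  Rhat 1.00
  sigma         0.0030  [0.0030]  95% CI (0.0029, 0.0032)  Rhat 1.00

held-out year 2019: R2 = 0.990, RMSE = 0.0029 Gcc units
  spring 50% date: predicted 94.6 vs observed 90.6 (|error| 4.1 d)
  autumn 50% date: predicted 277.4 vs observed 271.7 (|error| 5.8 d)
```

The temperature thresholds and sensitivities are recovered within their
credible intervals; the greenness bounds and observation noise are pinned
tightly by the long dormant and saturated segments; the switch day D is
only weakly identified (its posterior is wide) because midsummer nights
rarely cross the autumn threshold — shifting D inside that window changes
nothing observable. Held-out prediction explains 99% of greenness variance
and places both 50% transition dates within ~4–6 days.

The other examples cover site simulation (`01`), the camera pipeline
(`02`), flux processing (`03`), and band screening (`05`); each prints
what it computes and what the numbers mean.

A thin CLI mirrors the stages for shell use:

```
conipheno simulate --config site.yaml --out run/
conipheno indices --config site.yaml --roi run/roi_colors.csv --out run/
conipheno transitions --config site.yaml --composites run/composites.csv --out run/
```

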