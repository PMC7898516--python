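"""Coupled synthetic site generator for end-to-end pipeline testing.

Generates, from one fixed seed, a self-consistent set of inputs shaped like
the field data the pipeline consumes:

* daily weather: seasonal sinusoid + AR(1) anomalies + interannual offsets;
* a latent greenness trajectory driven by that weather through the
  temperature-based state model, observed with Gaussian noise, missing
  days, and snow-contaminated winter days;
* per-image ROI color records constructed by inverting the green chromatic
  coordinate so that recomputed indices recover the generated greenness;
* half-hourly fluxes whose Michaelis-Menten light-response capacity tracks
  the same latent greenness, plus Q10 respiration and noise;
* hyperspectral reflectance with pigment-driven features at the green
  (530 nm) and red (690 nm) bands, paired with pigment records.

All generators are deterministic for a fixed seed (independent substreams
per generator), and every dataset carries its ground truth so recovery can
be tested without external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .model import ModelParams, model_transitions, simulate_trajectory

__all__ = [
    "WeatherConfig",
    "FluxConfig",
    "CameraConfig",
    "SpectraConfig",
    "SyntheticSiteConfig",
    "GreennessSim",
    "default_model_params",
    "generate_weather",
    "generate_greenness",
    "generate_roi_colors",
    "generate_fluxes",
    "generate_spectra",
    "default_pigment_cycles",
]


def default_model_params() -> ModelParams:
    """Site-typical model parameters for a cold winter-dormant conifer site."""
    return ModelParams(
        theta1=5.0, theta2=0.0, rho1=0.002, rho2=0.003,
        d_switch=200.0, gamma_min=0.36, gamma_max=0.42, sigma=0.003,
    )


@dataclass
class WeatherConfig:
    # defaults emulate a cold-continental winter-dormant conifer site
    # (boreal/subalpine, annual mean near 2 deg C, strong synoptic anomalies)
    mean_temp: float = 2.0  # annual mean air temperature, deg C
    seasonal_amplitude: float = 14.0  # deg C, sinusoid half-range
    diurnal_range: float = 10.0  # deg C between tmin and tmax
    ar1: float = 0.7  # day-to-day anomaly persistence, [0, 1)
    noise_sd: float = 3.0  # stationary SD of the daily anomaly, deg C
    interannual_sd: float = 0.8  # SD of per-year mean offsets, deg C
    peak_doy: float = 196.0  # day of year of the temperature maximum

    def validate(self) -> None:
        if self.diurnal_range <= 0:
            raise ValueError("diurnal_range must be positive")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 must be in [0, 1)")
        if self.noise_sd < 0 or self.interannual_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class FluxConfig:
    km: float = 500.0  # half-saturation PPFD, umol m-2 s-1
    amax_peak: float = 20.0  # Amax at full greenness, umol m-2 s-1
    reco_base: float = 2.0  # respiration at 10 deg C, umol m-2 s-1
    q10: float = 2.0
    nee_noise_sd: float = 1.0  # umol m-2 s-1
    latitude: float = 45.0  # deg N, sets day length and peak PPFD
    ppfd_clear: float = 2400.0  # clear-sky noon PPFD at overhead sun
    ustar_threshold: float = 0.25  # m s-1, the "true" turbulence cutoff
    low_ustar_night_fraction: float = 0.3

    def validate(self) -> None:
        if self.km <= 0 or self.amax_peak < 0:
            raise ValueError("km must be > 0 and amax_peak >= 0")
        if self.nee_noise_sd < 0:
            raise ValueError("nee_noise_sd must be >= 0")
        if not (0.0 <= self.low_ustar_night_fraction <= 1.0):
            raise ValueError("low_ustar_night_fraction must be in [0, 1]")


@dataclass
class CameraConfig:
    brightness: float = 120.0  # mean per-channel DN of a canopy image
    red_fraction: float = 0.55  # share of the non-green total in the red channel
    illum_noise_sd: float = 2.0  # DN, per channel per image
    images_per_day: int = 5
    snow_prob: float = 0.15  # per eligible (cold) winter day
    snow_tmax: float = 2.0  # days with tmax below this can be snowy
    snow_blend_low: float = 0.6  # convex blend weight toward white, lower
    snow_blend_high: float = 0.95  # and upper bound
    snow_brightness: float = 235.0  # per-channel DN of a snowy scene

    def validate(self) -> None:
        if self.illum_noise_sd < 0:
            raise ValueError("illum_noise_sd must be >= 0")
        if not (0.0 <= self.snow_prob <= 1.0):
            raise ValueError("snow_prob must be in [0, 1]")
        if self.images_per_day < 1:
            raise ValueError("images_per_day must be >= 1")


@dataclass
class SpectraConfig:
    n_trees: int = 3
    wl_start: float = 400.0
    wl_stop: float = 900.0
    wl_step: float = 1.0
    base_level: float = 0.08  # reflectance level at the indicator bands
    alpha: float = 0.3  # fractional modulation of the 530/690 bands
    car_weight: float = 1.0  # green-band (carotenoid-pool) feature weight
    chl_weight: float = 1.0  # red-band (chlorophyll absorption) feature weight
    noise_sd: float = 0.0  # additive reflectance noise

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.wl_step <= 0 or self.wl_stop <= self.wl_start:
            raise ValueError("invalid wavelength grid")


@dataclass
class SyntheticSiteConfig:
    """One synthetic site: model truth + per-stream generator settings."""

    model_params: ModelParams = field(default_factory=default_model_params)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    flux: FluxConfig = field(default_factory=FluxConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    missing_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.missing_prob <= 1.0):
            raise ValueError("missing_prob must be in [0, 1]")
        self.weather.validate()
        self.flux.validate()
        self.camera.validate()
        self.spectra.validate()

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


_STREAM_WEATHER, _STREAM_GREEN, _STREAM_ROI, _STREAM_FLUX, _STREAM_SPECTRA = range(5)


def generate_weather(
    config: SyntheticSiteConfig, n_years: int, start_year: int = 2015
) -> pd.DataFrame:
    """Contiguous daily tmax/tmin: sinusoid + AR(1) anomaly + year offsets."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    config.validate()
    w = config.weather
    rng = config.rng(_STREAM_WEATHER)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = w.mean_temp + w.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - w.peak_doy) / 365.25
    )
    n = len(dates)
    innov = rng.normal(0.0, w.noise_sd * math.sqrt(1.0 - w.ar1**2), size=n)
    anomaly = lfilter([1.0], [1.0, -w.ar1], innov)
    year_offset = pd.Series(dates.year).map(
        {y: rng.normal(0.0, w.interannual_sd) for y in sorted(set(dates.year))}
    ).to_numpy()
    extra = rng.normal(0.0, 0.5 * w.noise_sd, size=n)
    tmax = seasonal + w.diurnal_range / 2.0 + anomaly + year_offset
    tmin = seasonal - w.diurnal_range / 2.0 + anomaly + extra + year_offset
    tmin = np.minimum(tmin, tmax)
    return pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin})


@dataclass
class GreennessSim:
    """Generated greenness with its ground truth."""

    observations: pd.DataFrame  # date, gcc, snow_flag (missing days absent)
    latent: pd.DataFrame  # date, gamma (every weather day)
    truth: dict  # params, true transition dates, per-day snow/missing masks


def generate_greenness(config: SyntheticSiteConfig, weather: pd.DataFrame) -> GreennessSim:
    """Observed daily greenness = latent trajectory + noise, snow, gaps."""
    config.validate()
    if weather.empty:
        raise ValueError("weather is empty")
    params = config.model_params
    latent = simulate_trajectory(params, weather, gamma_init=params.gamma_min)
    rng = config.rng(_STREAM_GREEN)
    n = len(latent)
    gcc = latent["gamma"].to_numpy() + rng.normal(0.0, params.sigma, size=n)

    cam = config.camera
    cold = weather["tmax"].to_numpy() < cam.snow_tmax
    snow = cold & (rng.random(n) < cam.snow_prob)
    blend = rng.uniform(cam.snow_blend_low, cam.snow_blend_high, size=n)
    gcc_snowy = (1.0 - blend) * gcc + blend * (1.0 / 3.0)
    gcc = np.where(snow, gcc_snowy, gcc)

    missing = rng.random(n) < config.missing_prob
    obs = pd.DataFrame(
        {"date": latent["date"], "gcc": gcc, "snow_flag": snow}
    ).loc[~missing].reset_index(drop=True)

    true_trans = model_transitions(params, weather, thresholds=(0.10, 0.25, 0.50))
    truth = {
        "params": params,
        "transitions": true_trans,
        "snow_mask": snow,
        "missing_mask": missing,
    }
    return GreennessSim(observations=obs, latent=latent, truth=truth)


def _solar_elevation_curve(hours: np.ndarray) -> np.ndarray:
    # stylized diurnal arc: 0 at 06:00/18:00, 60 deg at noon
    return 60.0 * np.sin(np.pi * (hours - 6.0) / 12.0)


def generate_roi_colors(config: SyntheticSiteConfig, greenness: pd.DataFrame) -> pd.DataFrame:
    """Per-image ROI color records whose recomputed Gcc matches the target.

    ``greenness`` needs columns date, gcc, snow_flag (as produced by
    :func:`generate_greenness`).  For each day, ``images_per_day`` midday
    records are emitted (plus two low-sun records to exercise solar
    filtering); channel DNs satisfy G/(R+G+B) = target Gcc before
    illumination noise and clipping.  Snow days are rendered bright and
    chromatically neutral.
    """
    config.validate()
    cam = config.camera
    g = np.asarray(greenness["gcc"], dtype=float)
    if np.any((g <= 0.0) | (g >= 1.0)):
        raise ValueError("target Gcc must lie in (0, 1)")
    rng = config.rng(_STREAM_ROI)

    midday_hours = np.linspace(9.0, 15.0, cam.images_per_day)
    rows = []
    for day, gcc_t, snow in zip(
        pd.to_datetime(greenness["date"]), g, greenness["snow_flag"].astype(bool)
    ):
        brightness = cam.snow_brightness if snow else cam.brightness
        red_frac = 0.5 if snow else cam.red_fraction
        total = 3.0 * brightness
        hours = np.concatenate([[5.5], midday_hours, [18.5]])
        for h in hours:
            g_dn = gcc_t * total
            r_dn = red_frac * (1.0 - gcc_t) * total
            b_dn = (1.0 - red_frac) * (1.0 - gcc_t) * total
            noise = rng.normal(0.0, cam.illum_noise_sd, size=3)
            r_dn, g_dn, b_dn = np.clip([r_dn + noise[0], g_dn + noise[1], b_dn + noise[2]],
                                       0.0, 255.0)
            hh = int(h)
            mm = int(round((h - hh) * 60))
            rows.append(
                {
                    "timestamp": day + pd.Timedelta(hours=hh, minutes=mm),
                    "r_dn": r_dn,
                    "g_dn": g_dn,
                    "b_dn": b_dn,
                    "solar_elevation": float(_solar_elevation_curve(np.array([h]))[0]),
                    "snow_flag": bool(snow),
                }
            )
    return pd.DataFrame(rows)


def generate_fluxes(
    config: SyntheticSiteConfig, greenness: pd.DataFrame, weather: pd.DataFrame
) -> pd.DataFrame:
    """Half-hourly NEE/PPFD/Tair/u* coupled to the latent greenness.

    ``greenness`` is the latent trajectory (date, gamma).  Amax scales
    linearly with normalized greenness, GPP follows the Michaelis-Menten
    light response, respiration follows a Q10 curve of air temperature, and
    NEE = Reco - GPP + noise under the micromet sign convention.  Truth
    columns gpp_true and reco_true are included for recovery tests.
    """
    config.validate()
    fx = config.flux
    params = config.model_params
    gdates = pd.to_datetime(greenness["date"]).to_numpy()
    wdates = pd.to_datetime(weather["date"]).to_numpy()
    if not np.array_equal(gdates, wdates):
        raise ValueError("greenness and weather must cover the same dates")
    rng = config.rng(_STREAM_FLUX)

    gamma = np.asarray(greenness["gamma"], dtype=float)
    rel = (gamma - params.gamma_min) / (params.gamma_max - params.gamma_min)
    amax_day = fx.amax_peak * np.clip(rel, 0.0, 1.0)
    doy = pd.DatetimeIndex(wdates).dayofyear.to_numpy(dtype=float)
    tmax = weather["tmax"].to_numpy(dtype=float)
    tmin = weather["tmin"].to_numpy(dtype=float)

    phi = math.radians(fx.latitude)
    decl = np.radians(23.44) * np.sin(2.0 * np.pi * (doy - 81.0) / 365.25)
    cos_h0 = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    h0 = np.arccos(cos_h0)
    daylen = 24.0 * h0 / np.pi
    sunrise = 12.0 - daylen / 2.0
    sin_noon = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl)
    ppfd_noon = fx.ppfd_clear * np.clip(sin_noon, 0.0, 1.0)

    hours = np.arange(48) / 2.0  # half-hour starts
    nd = len(wdates)
    hh = np.tile(hours, nd)
    day_idx = np.repeat(np.arange(nd), 48)

    frac = (hh - sunrise[day_idx]) / daylen[day_idx]
    ppfd = ppfd_noon[day_idx] * np.sin(np.pi * np.clip(frac, 0.0, 1.0))
    ppfd = np.where((frac > 0) & (frac < 1), np.maximum(ppfd, 0.0), 0.0)

    tmean = (tmax + tmin) / 2.0
    trange = tmax - tmin
    tair = tmean[day_idx] - (trange[day_idx] / 2.0) * np.cos(2.0 * np.pi * (hh - 4.0) / 24.0)

    gpp_true = amax_day[day_idx] * ppfd / (fx.km + ppfd)
    reco_true = fx.reco_base * fx.q10 ** ((tair - 10.0) / 10.0)
    nee = reco_true - gpp_true + rng.normal(0.0, fx.nee_noise_sd, size=nd * 48)

    night = ppfd < 5.0
    u = np.empty(nd * 48)
    u[~night] = rng.uniform(0.3, 0.7, size=(~night).sum())
    lows = rng.random(night.sum()) < fx.low_ustar_night_fraction
    night_u = np.where(
        lows,
        rng.uniform(0.02, fx.ustar_threshold, size=night.sum()),
        rng.uniform(fx.ustar_threshold, 0.7, size=night.sum()),
    )
    u[night] = night_u

    timestamps = np.repeat(wdates, 48) + np.tile(
        (np.arange(48) * np.timedelta64(30, "m")), nd
    )
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "nee": nee,
            "ppfd": ppfd,
            "tair": tair,
            "ustar": u,
            "gpp_true": gpp_true,
            "reco_true": reco_true,
        }
    )


def default_pigment_cycles(
    n_dates: int = 24, n_trees: int = 3, year: int = 2017, seed: int = 0
) -> pd.DataFrame:
    """Seasonal pigment pools for a few trees: constant chlorophyll, a
    carotenoid pool that swells in winter (photoprotection), and a
    xanthophyll-cycle pool tracking the carotenoids.  Units are arbitrary
    but positive; ratios carry the seasonal signal."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{year}-01-05", f"{year}-12-25", periods=n_dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    summer = 0.5 * (1.0 - np.cos(2.0 * np.pi * (doy - 15.0) / 365.25))  # 0 winter, 1 midsummer
    rows = []
    for tree in range(n_trees):
        chl = 100.0 * rng.uniform(0.95, 1.05)
        car_winter = 45.0 * rng.uniform(0.9, 1.1)
        car_summer = 22.0 * rng.uniform(0.9, 1.1)
        for d, s in zip(dates, summer):
            car = car_winter + (car_summer - car_winter) * s
            xan = 0.55 * car
            eps = float(np.clip(0.85 - 0.7 * s, 0.0, 1.0))
            rows.append(
                {
                    "date": d,
                    "tree_id": f"T{tree + 1}",
                    "chl": chl,
                    "car": car,
                    "xan": xan,
                    "chl_car": chl / car,
                    "chl_xan": chl / xan,
                    "eps": eps,
                }
            )
    return pd.DataFrame(rows)


def generate_spectra(
    config: SyntheticSiteConfig | SpectraConfig,
    pigments: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pigment-driven reflectance spectra on a 1 nm grid, 400-900 nm.

    Each spectrum is a smooth baseline with a red-edge rise, plus a
    green-band (530 nm) feature and minus a red-band (690 nm) chlorophyll
    absorption feature, both modulated by the record's chl:car ratio such
    that NDI(530, 690) is an exact linear function of the ratio when the
    two feature weights are equal and noise is zero.

    Returns (spectra frame: date, tree_id, one column per wavelength;
    the pigment frame actually used).
    """
    sp = config.spectra if isinstance(config, SyntheticSiteConfig) else config
    sp.validate()
    seed = config.seed if isinstance(config, SyntheticSiteConfig) else 0
    rng = np.random.default_rng([int(seed), _STREAM_SPECTRA])
    if pigments is None:
        pigments = default_pigment_cycles(n_trees=sp.n_trees, seed=seed)
    if (pigments[["chl", "car", "xan"]] <= 0).any().any():
        raise ValueError("pigment pools must be positive")

    wl = np.arange(sp.wl_start, sp.wl_stop + sp.wl_step / 2, sp.wl_step)
    baseline = 0.05 + 0.40 / (1.0 + np.exp(-(wl - 715.0) / 10.0))  # red edge
    g530 = np.exp(-0.5 * ((wl - 530.0) / 12.0) ** 2)
    g690 = np.exp(-0.5 * ((wl - 690.0) / 12.0) ** 2)

    ratio = pigments["chl_car"].to_numpy(dtype=float)
    lo, hi = ratio.min(), ratio.max()
    x = (ratio - lo) / (hi - lo) if hi > lo else np.zeros_like(ratio)  # 0 winter, 1 summer

    base530 = float(np.interp(530.0, wl, baseline))
    base690 = float(np.interp(690.0, wl, baseline))
    rows = []
    for i, (_, rec) in enumerate(pigments.iterrows()):
        target530 = sp.base_level * (1.0 + sp.alpha * x[i])
        target690 = sp.base_level * (1.0 - sp.alpha * x[i])
        spec = (
            baseline
            + sp.car_weight * (target530 - base530) * g530
            + sp.chl_weight * (target690 - base690) * g690
        )
        if sp.noise_sd > 0:
            spec = spec + rng.normal(0.0, sp.noise_sd, size=wl.size)
        spec = np.clip(spec, 0.0, 1.0)
        rows.append([rec["date"], rec["tree_id"], *spec])
    cols = ["date", "tree_id"] + [f"{w:.0f}" for w in wl]
    return pd.DataFrame(rows, columns=cols), pigments.reset_index(drop=True)
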