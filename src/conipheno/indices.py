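"""Camera color indices, leaf spectral indices, image filters, composites.

Per-image region-of-interest (ROI) mean digital numbers (8-bit, one value
per RGB channel) are reduced to chromatic indices:

* Gcc  = G / (R + G + B)        (green chromatic coordinate)
* GRVI = (G - R) / (G + R)      (green-red vegetation index)
* PRI  = (rho531 - rho570) / (rho531 + rho570)

Low-sun and snow-contaminated images are filtered before indices are
aggregated to 1- or 3-day composite products using a quantile statistic,
computed per image then aggregated (not aggregate-DN-then-index).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_gcc",
    "compute_grvi",
    "compute_pri",
    "filter_images",
    "composite",
    "snr",
]

log = logging.getLogger(__name__)

_STATISTICS = {
    "mean": lambda v: float(np.mean(v)),
    "median": lambda v: float(np.quantile(v, 0.50)),
    "q75": lambda v: float(np.quantile(v, 0.75)),
    "q90": lambda v: float(np.quantile(v, 0.90)),
}


def compute_gcc(r_dn, g_dn, b_dn):
    """Green chromatic coordinate G/(R+G+B). Vectorized; errors if R+G+B=0."""
    r = np.asarray(r_dn, dtype=float)
    g = np.asarray(g_dn, dtype=float)
    b = np.asarray(b_dn, dtype=float)
    total = r + g + b
    if np.any(total == 0):
        raise ValueError("degenerate input: R+G+B = 0")
    out = g / total
    return float(out) if out.ndim == 0 else out


def compute_grvi(r_dn, g_dn):
    """Green-red vegetation index (G-R)/(G+R). Errors if G+R=0."""
    r = np.asarray(r_dn, dtype=float)
    g = np.asarray(g_dn, dtype=float)
    total = g + r
    if np.any(total == 0):
        raise ValueError("degenerate input: G+R = 0")
    out = (g - r) / total
    return float(out) if out.ndim == 0 else out


def compute_pri(rho_531, rho_570):
    """Photochemical reflectance index (rho531-rho570)/(rho531+rho570)."""
    a = np.asarray(rho_531, dtype=float)
    b = np.asarray(rho_570, dtype=float)
    total = a + b
    if np.any(total == 0):
        raise ValueError("degenerate input: rho531+rho570 = 0")
    out = (a - b) / total
    return float(out) if out.ndim == 0 else out


def filter_images(
    records: pd.DataFrame,
    min_solar_elevation: float = 5.0,
    exclude_snow: bool = True,
    return_counts: bool = False,
):
    """Drop low-sun and (optionally) snow-flagged image records.

    ``records`` needs columns solar_elevation and snow_flag.  Ordering is
    preserved; removal counts are logged by reason.  An empty result is
    allowed.
    """
    low_sun = records["solar_elevation"] < min_solar_elevation
    snow = records["snow_flag"].astype(bool) & exclude_snow
    keep = ~(low_sun | snow)
    counts = {
        "low_sun": int(low_sun.sum()),
        "snow": int((snow & ~low_sun).sum()),
        "retained": int(keep.sum()),
    }
    log.info(
        "filter_images: removed %d low-sun, %d snow; retained %d of %d",
        counts["low_sun"], counts["snow"], counts["retained"], len(records),
    )
    out = records.loc[keep].reset_index(drop=True)
    if return_counts:
        return out, counts
    return out


def _window_assign(doy: np.ndarray, window_days: int) -> np.ndarray:
    # 3-d windows anchored at DOY 1 (1-3, 4-6, ...); composite sits on the
    # window's middle day
    return ((doy - 1) // window_days) * window_days + 1


def composite(
    records: pd.DataFrame,
    statistic: str = "q90",
    window_days: int = 1,
) -> pd.DataFrame:
    """Aggregate per-image indices to a 1- or 3-day composite product.

    Gcc and GRVI are computed per image, then reduced over all images in
    each window by the chosen statistic (mean | median | q75 | q90; linearly
    interpolated quantiles).  Windows with no images are absent.  Records
    are assumed already filtered.

    Returns columns date (window middle day), gcc, grvi, n_images, plus
    statistic and window metadata columns.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    if window_days not in (1, 3):
        raise ValueError("window_days must be 1 or 3")
    if records.empty:
        return pd.DataFrame(
            columns=["date", "gcc", "grvi", "n_images", "statistic", "window_days"]
        )
    df = records.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["gcc"] = compute_gcc(df["r_dn"], df["g_dn"], df["b_dn"])
    df["grvi"] = compute_grvi(df["r_dn"], df["g_dn"])
    year = ts.dt.year
    doy = ts.dt.dayofyear.to_numpy()
    win_start = _window_assign(doy, window_days)
    df["_year"] = year
    df["_win"] = win_start

    agg = _STATISTICS[statistic]
    rows = []
    for (yr, w), grp in df.groupby(["_year", "_win"], sort=True):
        mid_doy = w + (window_days - 1) // 2
        date = pd.Timestamp(int(yr), 1, 1) + pd.Timedelta(days=int(mid_doy) - 1)
        rows.append(
            {
                "date": date,
                "gcc": agg(grp["gcc"].to_numpy()),
                "grvi": agg(grp["grvi"].to_numpy()),
                "n_images": len(grp),
            }
        )
    out = pd.DataFrame(rows).sort_values("date").reset_index(drop=True)
    out["statistic"] = statistic
    out["window_days"] = window_days
    return out


def snr(series: pd.DataFrame, value_col: str = "gcc", span: float | None = None) -> float:
    """Seasonal signal-to-noise ratio of a greenness series.

    Signal is the seasonal amplitude of the LOESS-smoothed series; noise is
    the mean absolute difference between successive retained observations
    (day-to-day change is expected to be phenologically small).  Sites are
    usually screened at SNR >= 20:1 before model fitting.
    """
    from .phenology import loess_smooth

    if len(series) < 2:
        raise ValueError("snr requires more than one observation")
    dates = pd.to_datetime(series["date"])
    if (dates.max() - dates.min()).days < 365:
        raise ValueError("snr requires at least one full year of data")
    y = series[value_col].to_numpy(dtype=float)
    sm = loess_smooth(series["date"], y, span=span)
    amplitude = float(sm["value"].max() - sm["value"].min())
    noise = float(np.mean(np.abs(np.diff(y))))
    if noise == 0:
        warnings.warn("constant series: noise is zero, SNR undefined (+inf)")
        return float("inf")
    return amplitude / noise
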