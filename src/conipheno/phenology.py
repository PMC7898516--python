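"""Smoothing, outlier rejection, threshold transition dates, and agreement stats.

Seasonal transition dates (start/end of season, SOS/EOS) are defined as the
days on which a smoothed seasonal trajectory crosses predefined fractions
(10/25/50%) of either the seasonal amplitude (camera indices) or the annual
maximum (photosynthetic capacity).  Smoothing is locally weighted quadratic
regression (LOESS) with tricube weights and optional bisquare robustness
iterations; crossing days are linearly interpolated between bracketing
samples and required to be sustained to guard against noise-induced spikes.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "loess_smooth",
    "detect_outliers",
    "extract_transitions",
    "bootstrap_transitions",
    "sma_regression",
    "agreement_stats",
    "method_grid",
]


def _as_time_axis(x) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (numeric axis in days, datetime index or None)."""
    x = pd.Series(x)
    if np.issubdtype(x.dtype, np.datetime64) or x.dtype == object:
        dt = pd.to_datetime(x)
        t = (dt - dt.iloc[0]).dt.total_seconds().to_numpy() / 86400.0
        return t, dt.to_numpy()
    return x.to_numpy(dtype=float), None


def loess_smooth(
    x,
    y,
    span: float | None = None,
    robustify: bool = True,
    n_robust: int = 2,
    degree: int = 2,
) -> pd.DataFrame:
    """LOESS smoother with pointwise 95% intervals.

    Parameters
    ----------
    x : dates or numeric positions (must be sorted ascending)
    y : values
    span : fraction of the points in each local window, in (0, 1].
        Default (None) targets 0.3 of one seasonal cycle's points, so that
        multi-year series are not over-smoothed: span = 0.3 / n_years.
    robustify : run ``n_robust`` bisquare reweighting passes to downweight
        outliers
    degree : local polynomial degree (2 = locally quadratic)

    Returns a frame with columns date (or x), value, ci_low, ci_high.
    """
    t, dt = _as_time_axis(x)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("loess_smooth requires at least 10 points")
    if span is None:
        years = max((t[-1] - t[0]) / 365.25, 1.0) if dt is not None else 1.0
        span = min(1.0, 0.3 / years)
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    k = max(int(math.ceil(span * n)), degree + 2)
    if k > n:
        raise ValueError(f"span window of {k} points exceeds series length {n}")
    if np.any(np.diff(t) < 0):
        raise ValueError("x must be sorted ascending")

    # contiguous k-nearest windows for sorted x (two-pointer)
    starts = np.empty(n, dtype=int)
    lo = 0
    for i in range(n):
        hi = lo + k
        while hi < n and (t[i] - t[lo]) > (t[hi] - t[i]):
            lo += 1
            hi += 1
        starts[i] = lo
    win = starts[:, None] + np.arange(k)[None, :]  # n x k indices

    tw = t[win]
    yw = y[win]
    d = np.abs(tw - t[:, None])
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1.0 - np.clip(d / dmax, 0, 1) ** 3) ** 3

    robust_w = np.ones(n)
    for _ in range(n_robust + 1 if robustify else 1):
        ww = w * robust_w[win]
        # design: centered powers of t
        tc = tw - t[:, None]
        cols = [np.ones_like(tc)] + [tc**p for p in range(1, degree + 1)]
        X = np.stack(cols, axis=-1)  # n x k x (deg+1)
        WX = ww[..., None] * X
        XtWX = np.einsum("nkp,nkq->npq", X, WX)
        XtWy = np.einsum("nkp,nk->np", WX, yw)
        # ridge jitter guards near-singular windows (duplicate x)
        XtWX += 1e-12 * np.eye(degree + 1)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        fitted = beta[:, 0]
        # hat row for the fitted point: e1^T (X'WX)^-1 X'W
        inv = np.linalg.inv(XtWX)
        lvec = np.einsum("np,nkp->nk", inv[:, 0, :], WX)
        resid = y - fitted
        if robustify:
            mad = np.median(np.abs(resid))
            # a MAD at float-noise scale (exact local fits) means there is
            # nothing to robustify against
            if mad <= 1e-9 * max(float(np.std(y)), 1e-12):
                robust_w = np.ones(n)
            else:
                u = np.clip(resid / (6.0 * mad), -1.0, 1.0)
                robust_w = (1.0 - u**2) ** 2

    s2 = float(np.sum(robust_w * resid**2) / max(np.sum(robust_w) - (degree + 1), 1.0))
    se = np.sqrt(s2 * np.sum(lvec**2, axis=1))
    out = pd.DataFrame(
        {
            "date": dt if dt is not None else t,
            "value": fitted,
            "ci_low": fitted - 1.96 * se,
            "ci_high": fitted + 1.96 * se,
        }
    )
    return out


def detect_outliers(y, smoothed: pd.DataFrame, k: float = 4.0) -> np.ndarray:
    """Flag points whose residual from the smooth exceeds k x MAD."""
    y = np.asarray(y, dtype=float)
    resid = y - smoothed["value"].to_numpy()
    mad = np.median(np.abs(resid - np.median(resid)))
    # identical (or numerically exact) residuals carry no outlier signal
    if mad <= 1e-9 * max(float(np.std(y)), 1e-12):
        return np.zeros(y.size, dtype=bool)
    return np.abs(resid - np.median(resid)) > k * mad


def _crossing_day(doy: np.ndarray, v: np.ndarray, level: float, rising: bool, sustain: int):
    """First sustained crossing of ``level``; linear interpolation between
    the bracketing samples.  Returns fractional day of year or None."""
    above = v >= level if rising else v <= level
    n = v.size
    for i in range(1, n):
        if above[i] and not above[i - 1]:
            # sustained for >= `sustain` consecutive samples (or to the end)
            end = min(i + sustain, n)
            if above[i:end].all():
                v0, v1 = v[i - 1], v[i]
                if v1 == v0:
                    return float(doy[i])
                frac = (level - v0) / (v1 - v0)
                return float(doy[i - 1] + frac * (doy[i] - doy[i - 1]))
    return None


def extract_transitions(
    smoothed: pd.DataFrame,
    thresholds=(0.10, 0.25, 0.50),
    baseline_mode: str = "amplitude",
    min_sustained_days: int = 5,
    per_year: bool = True,
) -> pd.DataFrame:
    """Threshold-crossing transition dates from a smoothed seasonal series.

    ``baseline_mode='amplitude'`` places the threshold at
    min + f*(max - min) (camera-index convention); ``'annual_max'`` at
    f*max (photosynthetic-capacity convention).  One seasonal cycle per
    calendar year is assumed (Northern Hemisphere).  Rising crossings give
    SOS, falling crossings after the seasonal peak give EOS; a crossing must
    hold for ``min_sustained_days`` consecutive samples.

    Returns a frame: year, direction (rising|falling), threshold, doy,
    baseline, amplitude.
    """
    if baseline_mode not in ("amplitude", "annual_max"):
        raise ValueError("baseline_mode must be 'amplitude' or 'annual_max'")
    df = smoothed.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["doy"] = df["date"].dt.dayofyear

    whole_min = df["value"].min()
    whole_max = df["value"].max()

    rows = []
    for year, grp in df.groupby("year"):
        v = grp["value"].to_numpy(dtype=float)
        doy = grp["doy"].to_numpy(dtype=float)
        if per_year:
            vmin, vmax = float(v.min()), float(v.max())
        else:
            vmin, vmax = float(whole_min), float(whole_max)
        amp = vmax - vmin
        if amp <= 0 or (abs(vmax) > 0 and amp / max(abs(vmax), 1e-12) < 1e-9):
            warnings.warn(f"year {year}: flat series, no transitions extracted")
            continue
        peak = int(np.argmax(v))
        for f in thresholds:
            if baseline_mode == "amplitude":
                level = vmin + f * amp
            else:
                level = f * vmax
            sos = _crossing_day(
                doy[: peak + 1], v[: peak + 1], level, rising=True, sustain=min_sustained_days
            )
            if sos is not None:
                rows.append(
                    {
                        "year": int(year),
                        "direction": "rising",
                        "threshold": float(f),
                        "doy": sos,
                        "baseline": level,
                        "amplitude": amp,
                    }
                )
            eos = _crossing_day(
                doy[peak:], v[peak:], level, rising=False, sustain=min_sustained_days
            )
            if eos is not None:
                rows.append(
                    {
                        "year": int(year),
                        "direction": "falling",
                        "threshold": float(f),
                        "doy": eos,
                        "baseline": level,
                        "amplitude": amp,
                    }
                )
    cols = ["year", "direction", "threshold", "doy", "baseline", "amplitude"]
    return pd.DataFrame(rows, columns=cols)


def bootstrap_transitions(
    x,
    y,
    n_boot: int = 500,
    seed: int = 0,
    span: float | None = None,
    thresholds=(0.10, 0.25, 0.50),
    baseline_mode: str = "amplitude",
    min_sustained_days: int = 5,
) -> pd.DataFrame:
    """Transition dates with 2.5/97.5 percentile bootstrap intervals.

    Residuals about the LOESS smooth are resampled i.i.d., added back to
    the smooth, re-smoothed, and dates re-extracted per replicate.  A date
    that is absent in more than half of the replicates gets an undefined
    (NaN) interval and is flagged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    sm = loess_smooth(x, y, span=span)
    point = extract_transitions(
        sm, thresholds=thresholds, baseline_mode=baseline_mode,
        min_sustained_days=min_sustained_days,
    )
    resid = np.asarray(y, dtype=float) - sm["value"].to_numpy()
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_boot):
        yb = sm["value"].to_numpy() + rng.choice(resid, size=resid.size, replace=True)
        smb = loess_smooth(x, yb, span=span)
        tb = extract_transitions(
            smb, thresholds=thresholds, baseline_mode=baseline_mode,
            min_sustained_days=min_sustained_days,
        )
        samples.append(tb)
    allsamp = pd.concat(samples, ignore_index=True)
    key = ["year", "direction", "threshold"]
    counts = allsamp.groupby(key)["doy"].count().rename("n_boot_present")
    qs = (
        allsamp.groupby(key)["doy"]
        .quantile([0.025, 0.975])
        .unstack()
        .rename(columns={0.025: "ci_low_doy", 0.975: "ci_high_doy"})
    )
    out = point.merge(qs.reset_index(), on=key, how="left").merge(
        counts.reset_index(), on=key, how="left"
    )
    out["n_boot_present"] = out["n_boot_present"].fillna(0).astype(int)
    undefined = out["n_boot_present"] < (n_boot // 2)
    out.loc[undefined, ["ci_low_doy", "ci_high_doy"]] = np.nan
    out["ci_defined"] = ~undefined
    return out


def sma_regression(x, y) -> dict:
    """Standardized major axis (Type II) regression.

    slope = sign(r) * SD(y)/SD(x); intercept = mean(y) - slope*mean(x).
    Appropriate when both variables carry error, as when comparing two
    independently derived sets of transition dates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("sma_regression requires n >= 3")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return {"slope": float(slope), "intercept": intercept, "r": r, "n": int(x.size)}


def agreement_stats(dates_a, dates_b) -> dict:
    """Agreement between two paired sets of day-of-year values.

    Accepts arrays of paired days, or two transition-date frames which are
    matched on (year, direction, threshold).  Reports Pearson r, RMSE, MAE,
    mean bias (b - a, days), and n.
    """
    if isinstance(dates_a, pd.DataFrame):
        key = ["year", "direction", "threshold"]
        merged = dates_a.merge(dates_b, on=key, suffixes=("_a", "_b"))
        a = merged["doy_a"].to_numpy(dtype=float)
        b = merged["doy_b"].to_numpy(dtype=float)
    else:
        a = np.asarray(dates_a, dtype=float)
        b = np.asarray(dates_b, dtype=float)
    if a.size == 0:
        raise ValueError("no matched pairs")
    diff = b - a
    r = np.nan
    if a.size >= 2 and np.std(a) > 0 and np.std(b) > 0:
        r = float(np.corrcoef(a, b)[0, 1])
    return {
        "r": r,
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "mae": float(np.mean(np.abs(diff))),
        "bias": float(np.mean(diff)),
        "n": int(a.size),
    }


def method_grid(
    records: pd.DataFrame,
    gpp_dates: pd.DataFrame,
    statistics=("mean", "median", "q75", "q90"),
    thresholds=(0.10, 0.25, 0.50),
    indices=("gcc", "grvi"),
    window_days: int = 3,
    span: float | None = None,
) -> dict:
    """Evaluate all aggregation-statistic x threshold combinations.

    For each statistic and threshold (and each color index), composite the
    filtered image records, smooth, extract transition dates, and correlate
    SOS and EOS with the capacity-derived dates.  Combinations are ranked by
    aggregate correlation r(SOS) + r(EOS); cells with fewer than 3 matched
    year-pairs are marked not evaluable (NaN).

    Returns {"table": frame, "best": {index: row}}.
    """
    from .indices import composite

    rows = []
    for index_name in indices:
        for stat in statistics:
            comp = composite(records, statistic=stat, window_days=window_days)
            col = index_name
            sm = loess_smooth(comp["date"], comp[col], span=span)
            trans = extract_transitions(sm, thresholds=thresholds)
            for f in thresholds:
                cam = trans[trans["threshold"] == f]
                gpp_f = gpp_dates[np.isclose(gpp_dates["threshold"], f)]
                if gpp_f.empty:
                    gpp_f = gpp_dates[np.isclose(gpp_dates["threshold"], 0.5)]
                entry = {
                    "index": index_name,
                    "statistic": stat,
                    "threshold": float(f),
                    "r_sos": np.nan,
                    "r_eos": np.nan,
                }
                for direction, name in (("rising", "r_sos"), ("falling", "r_eos")):
                    c = cam[cam["direction"] == direction]
                    g = gpp_f[gpp_f["direction"] == direction]
                    m = c.merge(g, on="year", suffixes=("_cam", "_gpp"))
                    if len(m) >= 3 and np.std(m["doy_cam"]) > 0 and np.std(m["doy_gpp"]) > 0:
                        entry[name] = float(
                            np.corrcoef(m["doy_cam"], m["doy_gpp"])[0, 1]
                        )
                entry["aggregate"] = entry["r_sos"] + entry["r_eos"]
                entry["evaluable"] = np.isfinite(entry["aggregate"])
                rows.append(entry)
    table = pd.DataFrame(rows)
    best = {}
    for index_name in indices:
        sub = table[(table["index"] == index_name) & table["evaluable"]]
        if not sub.empty:
            best[index_name] = sub.loc[sub["aggregate"].idxmax()].to_dict()
    table = table.sort_values("aggregate", ascending=False).reset_index(drop=True)
    return {"table": table, "best": best}
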