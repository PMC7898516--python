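"""Half-hourly eddy-covariance fluxes -> daily photosynthetic capacity.

Workflow: u* screening of calm nights, look-up-table gap-filling, nighttime
ecosystem respiration (Reco) over a moving 5-day window, flux partitioning
GPP = Reco - NEE (micrometeorological sign convention: NEE < 0 is net
uptake), a Michaelis-Menten light-response fit per moving window

    GPP = Amax * PPFD / (Km + PPFD)

and photosynthetic capacity GPPsat = fit evaluated at saturating light
(PPFD = 2000 umol m-2 s-1).  Seasonal transition dates are threshold
crossings of the smoothed daily GPPsat series at fractions of its annual
maximum.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ustar_filter",
    "gapfill",
    "estimate_reco",
    "partition_gpp",
    "fit_light_response",
    "gppsat_series_to_transitions",
    "GPPSAT_PPFD",
    "NIGHT_PPFD",
]

log = logging.getLogger(__name__)

GPPSAT_PPFD = 2000.0  # full-sun PPFD at which capacity is evaluated
NIGHT_PPFD = 5.0  # below this PPFD a half-hour counts as night


def _require_cols(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"flux records missing columns: {missing}")


def ustar_filter(records: pd.DataFrame, threshold="auto") -> pd.DataFrame:
    """Gap-flag calm-night records (u* below threshold, PPFD < 5).

    ``threshold='auto'`` estimates the u* value above which binned
    nighttime NEE plateaus: nighttime records are binned by u* quantiles,
    and the threshold is the first bin whose mean NEE reaches 95% of the
    plateau level (mean of the top three bins).  Daytime records are never
    flagged.
    """
    _require_cols(records, ["ppfd", "ustar", "nee"])
    df = records.copy()
    if "gap_flag" not in df.columns:
        df["gap_flag"] = False
    night = df["ppfd"] < NIGHT_PPFD
    if threshold == "auto":
        sub = df.loc[night & df["nee"].notna() & df["ustar"].notna()]
        if len(sub) < 100:
            raise ValueError("too few nighttime records for automatic u* threshold")
        n_bins = 20
        edges = np.quantile(sub["ustar"], np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, sub["ustar"], side="right") - 1, 0, n_bins - 1)
        means = np.array(
            [sub["nee"].to_numpy()[idx == b].mean() if (idx == b).any() else np.nan
             for b in range(n_bins)]
        )
        plateau = np.nanmean(means[-3:])
        ok = np.where(means >= 0.95 * plateau)[0]
        bin_lo = ok[0] if ok.size else n_bins - 1
        threshold = float(edges[bin_lo])
        log.info("auto u* threshold: %.3f m s-1", threshold)
    flag = night & (df["ustar"] < threshold)
    if night.any() and flag[night].all():
        warnings.warn("u* threshold removes every nighttime record")
    df.loc[flag, "gap_flag"] = True
    df.attrs["ustar_threshold"] = float(threshold)
    return df


def gapfill(
    records: pd.DataFrame,
    max_gap_fraction: float = 0.4,
    ppfd_tol: float = 200.0,
    tair_tol: float = 2.5,
    day_window: int = 7,
    min_donors: int = 3,
    max_widenings: int = 3,
) -> pd.DataFrame:
    """Fill gap-flagged NEE with a similarity look-up table.

    Each gap is imputed by the mean NEE of same-hour observations within
    +/- ``day_window`` days whose PPFD and air temperature lie within the
    tolerances; the window and tolerances double until at least
    ``min_donors`` donors exist (at most ``max_widenings`` doublings).
    Unfillable gaps remain missing and are reported.  Filled records carry
    ``filled_flag``.
    """
    _require_cols(records, ["timestamp", "nee", "ppfd", "tair"])
    df = records.copy()
    if "gap_flag" not in df.columns:
        df["gap_flag"] = df["nee"].isna()
    else:
        df["gap_flag"] = df["gap_flag"] | df["nee"].isna()
    frac = df["gap_flag"].mean()
    if frac > max_gap_fraction:
        raise ValueError(f"gap fraction {frac:.0%} exceeds {max_gap_fraction:.0%}")
    df["filled_flag"] = False
    if not df["gap_flag"].any():
        return df

    ts = pd.to_datetime(df["timestamp"])
    day = (ts - ts.iloc[0]).dt.days.to_numpy()
    hour = ts.dt.hour.to_numpy()
    nee = df["nee"].to_numpy(dtype=float)
    ppfd = df["ppfd"].to_numpy(dtype=float)
    tair = df["tair"].to_numpy(dtype=float)
    good = ~df["gap_flag"].to_numpy()

    unfilled = 0
    for i in np.flatnonzero(df["gap_flag"].to_numpy()):
        dw, pt, tt = day_window, ppfd_tol, tair_tol
        value = None
        for _ in range(max_widenings + 1):
            cand = (
                good
                & (hour == hour[i])
                & (np.abs(day - day[i]) <= dw)
                & (np.abs(ppfd - ppfd[i]) <= pt)
                & (np.abs(tair - tair[i]) <= tt)
            )
            if cand.sum() >= min_donors:
                value = float(np.nanmean(nee[cand]))
                break
            dw, pt, tt = dw * 2, pt * 2, tt * 2
        if value is None:
            unfilled += 1
            continue
        df.iloc[i, df.columns.get_loc("nee")] = value
        df.iloc[i, df.columns.get_loc("filled_flag")] = True
    if unfilled:
        log.warning("gapfill: %d gaps unfillable after maximum widening", unfilled)
    df.attrs["n_unfilled"] = unfilled
    return df


def estimate_reco(records: pd.DataFrame, window_days: int = 5) -> pd.DataFrame:
    """Daily ecosystem respiration from nighttime NEE in a centered window.

    For each day, Reco is the mean of retained (non-gap, non-filled-as-gap)
    nighttime NEE over the centered ``window_days`` window; days whose
    window holds no nighttime observation get a missing Reco.
    Returns a frame: date, reco, n_night_obs.
    """
    _require_cols(records, ["timestamp", "nee", "ppfd"])
    df = records.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["_date"] = ts.dt.normalize()
    retained = (~df.get("gap_flag", pd.Series(False, index=df.index))) & df["nee"].notna()
    night = df["ppfd"] < NIGHT_PPFD
    nd = df.loc[night & retained]
    sums = nd.groupby("_date")["nee"].agg(["sum", "count"])
    all_days = pd.date_range(df["_date"].min(), df["_date"].max(), freq="D")
    sums = sums.reindex(all_days, fill_value=0.0)
    half = window_days // 2
    roll_sum = sums["sum"].rolling(window_days, center=True, min_periods=1).sum()
    roll_cnt = sums["count"].rolling(window_days, center=True, min_periods=1).sum()
    reco = roll_sum / roll_cnt.replace(0, np.nan)
    return pd.DataFrame(
        {"date": all_days, "reco": reco.to_numpy(), "n_night_obs": roll_cnt.to_numpy(dtype=int)}
    )


def partition_gpp(records: pd.DataFrame, reco: pd.DataFrame) -> pd.DataFrame:
    """Half-hourly GPP = Reco - NEE, floored at zero.

    Under the micromet sign convention (NEE negative = uptake), subtracting
    NEE from respiration yields photosynthetic uptake as a positive flux.
    Negative values (noise around zero at night) are floored at 0 and
    counted in ``attrs['n_floored']``.  Adds columns reco, gpp.
    """
    df = records.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["_date"] = ts.dt.normalize()
    rmap = reco.set_index(pd.to_datetime(reco["date"]))["reco"]
    df["reco"] = df["_date"].map(rmap)
    gpp = df["reco"] - df["nee"]
    n_floored = int((gpp < 0).sum())
    df["gpp"] = gpp.clip(lower=0.0)
    df.drop(columns="_date", inplace=True)
    df.attrs["n_floored"] = n_floored
    return df


def _mm(ppfd, amax, km):
    return amax * ppfd / (km + ppfd)


def fit_light_response(
    records: pd.DataFrame,
    window_days: int = 5,
    step_days: int = 1,
    min_obs: int = 20,
    amax_bounds=(0.0, 100.0),
    km_bounds=(1.0, 5000.0),
) -> pd.DataFrame:
    """Moving-window Michaelis-Menten fits of daytime GPP on PPFD.

    Nonlinear least squares per centered window, with three starting points
    (Michaelis-Menten fits are ill-conditioned when light never saturates);
    the best-SSE converged fit wins.  Windows with fewer than ``min_obs``
    daytime observations, or with no PPFD spread, are flagged
    non-converged and excluded downstream.

    Returns: window_center_date, amax, km, gpp_sat, n_obs, converged,
    resid_sd.
    """
    _require_cols(records, ["timestamp", "gpp", "ppfd"])
    df = records.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["_date"] = ts.dt.normalize()
    daytime = (df["ppfd"] >= NIGHT_PPFD) & df["gpp"].notna()
    day_df = df.loc[daytime, ["_date", "ppfd", "gpp"]]
    days = pd.date_range(df["_date"].min(), df["_date"].max(), freq=f"{step_days}D")
    half = pd.Timedelta(days=window_days / 2.0)

    grouped = {d: g for d, g in day_df.groupby("_date")}
    rows = []
    for center in days:
        window_days_list = pd.date_range(
            center - pd.Timedelta(days=window_days // 2),
            center + pd.Timedelta(days=window_days // 2),
            freq="D",
        )
        parts = [grouped[d] for d in window_days_list if d in grouped]
        row = {
            "window_center_date": center,
            "amax": np.nan,
            "km": np.nan,
            "gpp_sat": np.nan,
            "n_obs": 0,
            "converged": False,
            "resid_sd": np.nan,
        }
        if parts:
            sub = pd.concat(parts)
            row["n_obs"] = len(sub)
            x = sub["ppfd"].to_numpy(dtype=float)
            y = sub["gpp"].to_numpy(dtype=float)
            if len(sub) >= min_obs and np.ptp(x) > 50.0:
                best = None
                for amax0, km0 in ((10.0, 500.0), (30.0, 1000.0), (5.0, 100.0)):
                    try:
                        popt, _ = curve_fit(
                            _mm, x, y, p0=(amax0, km0),
                            bounds=(
                                (amax_bounds[0], km_bounds[0]),
                                (amax_bounds[1], km_bounds[1]),
                            ),
                            maxfev=2000,
                        )
                    except RuntimeError:
                        continue
                    sse = float(np.sum((y - _mm(x, *popt)) ** 2))
                    if best is None or sse < best[0]:
                        best = (sse, popt)
                if best is not None:
                    sse, (amax, km) = best
                    row.update(
                        amax=float(amax),
                        km=float(km),
                        gpp_sat=float(_mm(GPPSAT_PPFD, amax, km)),
                        converged=True,
                        resid_sd=float(np.sqrt(sse / max(len(sub) - 2, 1))),
                    )
        rows.append(row)
    return pd.DataFrame(rows)


def gppsat_series_to_transitions(
    fits: pd.DataFrame,
    thresholds=(0.10, 0.25, 0.50),
    span: float | None = None,
    n_boot: int | None = None,
    seed: int = 0,
    non_dormant_fraction: float = 0.2,
) -> pd.DataFrame:
    """Transition dates of the smoothed daily GPPsat series.

    Thresholds are fractions of the per-year annual maximum of the
    LOESS-smoothed GPPsat (``baseline_mode='annual_max'``).  Sites whose
    annual minimum exceeds ``non_dormant_fraction`` of the maximum are not
    winter dormant; their dates are still computed but flagged.
    Optionally bootstraps confidence intervals.
    """
    from .phenology import bootstrap_transitions, extract_transitions, loess_smooth

    ok = fits.loc[fits["converged"] & fits["gpp_sat"].notna()]
    if ok.empty:
        return pd.DataFrame(
            columns=["year", "direction", "threshold", "doy", "baseline", "amplitude",
                     "non_dormant"]
        )
    dates = pd.to_datetime(ok["window_center_date"])
    if (dates.max() - dates.min()).days < 300:
        raise ValueError("need about a year of capacity fits to extract transitions")
    y = ok["gpp_sat"].to_numpy(dtype=float)
    if np.allclose(y, 0.0):
        return pd.DataFrame(
            columns=["year", "direction", "threshold", "doy", "baseline", "amplitude",
                     "non_dormant"]
        )
    if n_boot:
        trans = bootstrap_transitions(
            dates, y, n_boot=n_boot, seed=seed, span=span,
            thresholds=thresholds, baseline_mode="annual_max",
        )
    else:
        sm = loess_smooth(dates, y, span=span)
        trans = extract_transitions(sm, thresholds=thresholds, baseline_mode="annual_max")
    sm_all = loess_smooth(dates, y, span=span)
    sm_all["year"] = pd.to_datetime(sm_all["date"]).dt.year
    flags = {}
    for year, grp in sm_all.groupby("year"):
        vmax = grp["value"].max()
        vmin = max(grp["value"].min(), 0.0)
        flags[year] = bool(vmax > 0 and vmin > non_dormant_fraction * vmax)
    trans["non_dormant"] = trans["year"].map(flags)
    if trans["non_dormant"].any():
        warnings.warn("some years flagged non-dormant: winter capacity floor exceeds "
                      f"{non_dormant_fraction:.0%} of the annual maximum")
    return trans
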