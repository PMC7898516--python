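"""Two-band normalized-difference screening of hyperspectral reflectance.

Canopy reflectance spectra (400-900 nm) are screened exhaustively: the
normalized difference index NDI(l1, l2) = (rho_l1 - rho_l2)/(rho_l1 +
rho_l2) is computed for every wavelength pair and correlated against a
pigment trait (typically the chlorophyll:carotenoid ratio) over the
measurement dates, producing an antisymmetric Pearson-r heatmap from which
the best band pair is read off.  A broadband camera can be emulated by
integrating spectra against per-channel quantum-efficiency curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_ndi",
    "correlation_map",
    "best_bands",
    "simulate_camera_rgb",
    "default_camera_response",
]


def _snap(grid: np.ndarray, lam: float) -> int:
    step = np.median(np.diff(grid))
    i = int(np.argmin(np.abs(grid - lam)))
    if abs(grid[i] - lam) > step / 2 + 1e-9:
        raise ValueError(f"wavelength {lam} nm not on the grid (step {step} nm)")
    return i


def compute_ndi(wavelengths, reflectance, lambda1: float, lambda2: float):
    """NDI between two bands; nearest-grid snap within half a step.

    ``reflectance`` may be 1-D (one spectrum) or 2-D (dates x wavelengths);
    returns a scalar or a per-date vector.
    """
    wl = np.asarray(wavelengths, dtype=float)
    rho = np.asarray(reflectance, dtype=float)
    i1, i2 = _snap(wl, lambda1), _snap(wl, lambda2)
    a = rho[..., i1]
    b = rho[..., i2]
    total = a + b
    if np.any(total == 0):
        raise ValueError("zero denominator in NDI")
    out = (a - b) / total
    return float(out) if out.ndim == 0 else out


def correlation_map(wavelengths, reflectance, trait) -> np.ndarray:
    """Pearson r of NDI(l1, l2) vs trait for every wavelength pair.

    ``reflectance`` is (n_dates, n_wavelengths); ``trait`` is length
    n_dates with positive variance.  Returns an antisymmetric-in-sign
    (r[i,j] = -r[j,i]) matrix; cells whose NDI series is constant are NaN.
    Requires >= 4 matched dates.
    """
    wl = np.asarray(wavelengths, dtype=float)
    rho = np.asarray(reflectance, dtype=float)
    y = np.asarray(trait, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != y.size:
        raise ValueError("reflectance must be (n_dates, n_wavelengths) matching trait")
    if y.size < 4:
        raise ValueError("correlation_map requires >= 4 matched dates")
    if np.std(y) == 0:
        raise ValueError("trait has zero variance")
    n, m = rho.shape
    yc = (y - y.mean()) / (np.std(y) + 0.0)
    # NDI for all pairs, date-blocked to bound memory
    a = rho[:, :, None]
    b = rho[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ndi = (a - b) / (a + b)  # n x m x m
    mean = np.nanmean(ndi, axis=0)
    sd = np.nanstd(ndi, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ndi - mean) / sd
        r = np.einsum("nij,n->ij", np.nan_to_num(z), yc) / n
    r[sd == 0] = np.nan
    np.fill_diagonal(r, np.nan)
    return r


def best_bands(rmap: np.ndarray, wavelengths) -> tuple[float, float, float]:
    """Band pair with the largest |r|; ties go to the smallest l1 then l2."""
    wl = np.asarray(wavelengths, dtype=float)
    absr = np.abs(rmap)
    if np.all(np.isnan(absr)):
        raise ValueError("correlation map is fully masked")
    best = np.nanmax(absr)
    cand = np.argwhere(np.isclose(absr, best, rtol=0, atol=1e-12))
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    i, j = cand[0]
    return float(wl[i]), float(wl[j]), float(rmap[i, j])


def default_camera_response(wavelengths) -> dict[str, np.ndarray]:
    """Nominal RGB quantum-efficiency curves for a consumer camera sensor.

    Gaussian passbands centered near 610 (R), 535 (G), 460 (B) nm with
    ~50 nm full width; synthetic but shaped like published phenocam
    channel responses.
    """
    wl = np.asarray(wavelengths, dtype=float)

    def gauss(center, width):
        return np.exp(-0.5 * ((wl - center) / width) ** 2)

    return {"r": gauss(610.0, 35.0), "g": gauss(535.0, 30.0), "b": gauss(460.0, 25.0)}


def simulate_camera_rgb(
    wavelengths,
    reflectance,
    response: dict[str, np.ndarray] | None = None,
    gain: float = 10.0,
) -> tuple[float, float, float]:
    """Broadband RGB digital numbers from a spectrum.

    Each channel DN is the trapezoid-rule integral of response(l) * rho(l),
    scaled by a common gain and clipped to [0, 255].
    """
    wl = np.asarray(wavelengths, dtype=float)
    rho = np.asarray(reflectance, dtype=float)
    if response is None:
        response = default_camera_response(wl)
    dns = []
    for ch in ("r", "g", "b"):
        resp = np.asarray(response[ch], dtype=float)
        if resp.shape != wl.shape:
            raise ValueError("response curves must share the wavelength grid")
        if np.any(resp < 0):
            raise ValueError("response curves must be nonnegative")
        if np.all(resp == 0):
            raise ValueError(f"all-zero response for channel {ch!r}")
        raw = np.trapezoid(resp * rho, wl)
        dns.append(float(np.clip(gain * raw, 0.0, 255.0)))
    return tuple(dns)
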