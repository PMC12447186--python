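"""Reverberant-field wavenumber estimation (RevOCE comparator).

For a fully diffuse (reverberant) shear-wave ensemble — waves arriving from
all directions and orientations uniformly over the sphere — the spatial
autocorrelation of the z displacement over a lateral lag r follows the
spherical-Bessel combination

    B(r) = j0(x) - j1(x)/x,   x = 2*pi*k*r,

with B(0) = 2/3 before normalization. The estimator: per 6x6-pixel window,
take the normalized real part of the 2D autocorrelation, azimuthally average
it into a radial profile, and least-squares fit B (rescaled to 1 at zero lag)
for k. The fit range ends at the profile's second zero crossing when one lies
within the window, else the whole profile is used. The per-window map is
upsampled to the DPGA map grid and smoothed with sigma = 2 windows.

The diffuse assumption is the method's limitation: a single plane wave or a
wavelength exceeding the window extent biases the fit (diagnosed by the
residual, reproduced in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, zoom
from scipy.optimize import least_squares
from scipy.special import spherical_jn

from .dpga import KMap, WindowSpec, _smooth_nan, k_to_speed_modulus, windowed_autocorrelation

__all__ = [
    "BesselFitResult",
    "bessel_model",
    "radial_ac_profile",
    "azimuthal_average_rays",
    "fit_k",
    "revoce_map",
]


@dataclass
class BesselFitResult:
    """Outcome of one windowed spherical-Bessel fit."""

    k_hat: float
    rss: float
    fit_range_m: float
    converged: bool
    window_index: tuple = (0, 0)


def bessel_model(k: float, dr, *, two_pi_convention: bool = True, rescale: bool = True) -> np.ndarray:
    """Reverberant-field autocorrelation model at wavenumber k (cycles/m).

    Evaluates j0(x) - j1(x)/x at x = 2*pi*k*dr (set ``two_pi_convention=False``
    for x = k*dr with k in rad/m). The x -> 0 limit is 1 - 1/3 = 2/3, handled
    analytically; ``rescale=True`` divides by 2/3 so the model is 1 at zero
    lag, matching a normalized data profile.
    """
    dr = np.asarray(dr, dtype=float)
    x = (2 * np.pi * k * dr) if two_pi_convention else (k * dr)
    x = np.abs(x)
    out = np.empty_like(x)
    small = x < 1e-6
    out[small] = 2.0 / 3.0 - 2.0 * x[small] ** 2 / 15.0  # series: 2/3 - 2x^2/15 + O(x^4)
    xs = x[~small]
    out[~small] = spherical_jn(0, xs) - spherical_jn(1, xs) / xs
    if rescale:
        out = out * 1.5
    return out


def _ac_window_real(field: np.ndarray, win: WindowSpec) -> tuple:
    """(nwx, nwy, P, P) normalized real autocorrelation per window + energies.

    The raw linear autocorrelation of a w x w window carries a triangular
    taper — lag d sums only (w-|dx|)(w-|dy|) products — which would mimic a
    faster model decay and bias fitted wavenumbers high. Dividing by the
    overlap count gives the unbiased estimate the ensemble model expects.
    """
    acd = windowed_autocorrelation(field, win)
    ac = acd["ac"]
    c = acd["center"]
    w = acd["w"]
    P = ac.shape[-1]
    lag = np.abs(np.arange(P) - c)
    count = np.maximum(w - lag[:, None], 0) * np.maximum(w - lag[None, :], 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = ac * (w * w / np.where(count > 0, count, 1))
    e0 = ac[..., c, c].real
    with np.errstate(invalid="ignore", divide="ignore"):
        acn = ac.real / e0[..., None, None]
    return acn, e0, c


def radial_ac_profile(
    enface_field: np.ndarray,
    win: WindowSpec | None = None,
    dx: float = 1.0,
) -> dict:
    """Azimuthally averaged, normalized real autocorrelation per window.

    Per window: linear 2D autocorrelation, real part, normalized to 1 at zero
    lag, then binned by lag radius (bin width = one pixel pitch). Returns
    ``lags`` (m), ``profiles`` (nwx, nwy, n_bins), ``valid`` (windows with
    non-zero energy) and ``counts`` (lags per bin).
    """
    win = win or WindowSpec(w=6)
    acn, e0, c = _ac_window_real(np.asarray(enface_field), win)
    P = acn.shape[-1]
    ii = np.arange(P) - c
    R = np.hypot(ii[:, None], ii[None, :]) * dx
    max_lag = (win.w - 1) * dx
    n_bins = win.w  # bins at 0, dx, ..., (w-1)*dx
    bin_idx = np.round(R / dx).astype(int)
    keep = (R <= max_lag + 1e-12) & (bin_idx < n_bins)
    profiles = np.zeros(acn.shape[:2] + (n_bins,))
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = keep & (bin_idx == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            profiles[..., b] = acn[..., sel].mean(axis=-1)
    lags = np.arange(n_bins) * dx
    valid = e0 > 0
    return {"lags": lags, "profiles": profiles, "valid": valid, "counts": counts}


def azimuthal_average_rays(ac_image: np.ndarray, center: int, dx: float, n_angles: int = 64) -> tuple:
    """Azimuthal average of one autocorrelation image by ray sampling.

    Samples the image along rays at ``n_angles`` azimuths with linear
    interpolation and averages — the rotation/Radon-style comparator for the
    radial-binning path. Returns (lags, profile).
    """
    P = ac_image.shape[0]
    n_r = min(center, P - 1 - center) + 1
    r = np.arange(n_r)
    th = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    xs = center + np.outer(np.cos(th), r)
    ys = center + np.outer(np.sin(th), r)
    vals = map_coordinates(ac_image, np.stack([xs.ravel(), ys.ravel()]), order=1)
    prof = vals.reshape(n_angles, n_r).mean(axis=0)
    return r * dx, prof


def _second_zero_crossing(lags: np.ndarray, profile: np.ndarray) -> float | None:
    """Lag of the second sign change (linear interpolation), or None."""
    s = np.sign(profile)
    crossings = []
    for i in range(len(profile) - 1):
        if s[i] != 0 and s[i + 1] != 0 and s[i] != s[i + 1]:
            f = profile[i] / (profile[i] - profile[i + 1])
            crossings.append(lags[i] + f * (lags[i + 1] - lags[i]))
        elif s[i + 1] == 0:
            crossings.append(lags[i + 1])
    if len(crossings) >= 2:
        return float(crossings[1])
    return None


# first zero of j0(x) - j1(x)/x, found once by bisection
def _model_first_zero() -> float:
    from scipy.optimize import brentq

    return brentq(lambda x: bessel_model(1.0, x / (2 * np.pi), rescale=False), 1.0, 4.0)


_X1 = _model_first_zero()


def fit_k(
    profile: np.ndarray,
    lags: np.ndarray,
    init_k: float | None = None,
    *,
    two_pi_convention: bool = True,
) -> BesselFitResult:
    """Least-squares fit of the reverberant model to one radial profile.

    The fit uses lags up to the profile's second zero crossing when one exists
    within the maximum lag, else the entire profile. Initialization places the
    model's first zero at the profile's first zero crossing (bounded solver).
    """
    profile = np.asarray(profile, float)
    lags = np.asarray(lags, float)
    if profile.shape != lags.shape or profile.size < 3:
        raise ValueError("profile and lags must match and have >= 3 samples")

    z2 = _second_zero_crossing(lags, profile)
    max_lag = z2 if z2 is not None else float(lags[-1])
    sel = lags <= max_lag + 1e-12
    if sel.sum() < 3:
        sel = np.ones_like(sel)

    if init_k is None:
        s = np.sign(profile)
        first = None
        for i in range(len(profile) - 1):
            if s[i] > 0 and s[i + 1] <= 0:
                f = profile[i] / (profile[i] - profile[i + 1])
                first = lags[i] + f * (lags[i + 1] - lags[i])
                break
        if first is not None and first > 0:
            init_k = _X1 / (2 * np.pi * first) if two_pi_convention else _X1 / first
        else:
            init_k = 0.5 / lags[-1]  # half a cycle across the window

    span = float(lags[-1] - lags[0]) or 1.0
    lo, hi = 1e-3 / span, (20.0 if two_pi_convention else 2 * np.pi * 20.0) / span
    x0 = float(np.clip(init_k, lo, hi))

    def resid(p):
        return bessel_model(p[0], lags[sel], two_pi_convention=two_pi_convention) - profile[sel]

    try:
        sol = least_squares(resid, x0=[x0], bounds=([lo], [hi]))
        k_hat = float(sol.x[0])
        rss = float(np.sum(sol.fun**2))
        converged = bool(sol.success) and lo * 1.01 < k_hat < hi * 0.99
    except Exception:
        k_hat, rss, converged = float("nan"), float("inf"), False
    return BesselFitResult(k_hat=k_hat, rss=rss, fit_range_m=float(max_lag), converged=converged)


def revoce_map(
    enface_field: np.ndarray,
    dx: float,
    dy: float,
    *,
    win: WindowSpec | None = None,
    upsample_to: tuple | None = None,
    smooth_sigma_windows: float = 2.0,
    f0_hz: float | None = None,
    rho_kg_m3: float = 1000.0,
    two_pi_convention: bool = True,
) -> KMap:
    """Per-window reverberant-model k map, upsampled and smoothed.

    Runs the radial-profile fit in every 6x6 window of the en-face field,
    upsamples the (nwx, nwy) map to ``upsample_to`` (e.g. the 35x35 DPGA map
    grid) and applies Gaussian smoothing with sigma of two windows expressed
    on the upsampled grid. Non-converged windows become NaN.
    """
    win = win or WindowSpec(w=6)
    field = np.asarray(enface_field)
    prof = radial_ac_profile(field, win, dx)
    nwx, nwy = prof["profiles"].shape[:2]
    k = np.full((nwx, nwy), np.nan)
    rss = np.full((nwx, nwy), np.nan)
    for i in range(nwx):
        for j in range(nwy):
            if not prof["valid"][i, j]:
                continue
            res = fit_k(prof["profiles"][i, j], prof["lags"], two_pi_convention=two_pi_convention)
            if res.converged:
                k[i, j] = res.k_hat
                rss[i, j] = res.rss

    sigma_up = float(smooth_sigma_windows)
    if upsample_to is not None and (nwx, nwy) != tuple(upsample_to):
        fy = upsample_to[0] / nwx
        fx = upsample_to[1] / nwy
        valid = np.isfinite(k)
        filled = np.where(valid, k, np.nanmedian(k) if np.any(valid) else 0.0)
        k_up = zoom(filled, (fy, fx), order=1, grid_mode=True, mode="nearest")
        v_up = zoom(valid.astype(float), (fy, fx), order=1, grid_mode=True, mode="nearest")
        k = np.where(v_up > 0.5, k_up, np.nan)
        sigma_up = smooth_sigma_windows * (fy + fx) / 2.0
    k = _smooth_nan(k, sigma_up)

    c = G = None
    if f0_hz is not None:
        c, G = k_to_speed_modulus(k, f0_hz, rho_kg_m3)
    return KMap(
        k=k, c=c, G=G,
        meta={
            "method": "revoce", "w": win.w, "smooth_sigma_windows": smooth_sigma_windows,
            "rss_median": float(np.nanmedian(rss)) if np.any(np.isfinite(rss)) else float("nan"),
            "two_pi_convention": two_pi_convention,
        },
    )
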