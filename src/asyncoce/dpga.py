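"""Directional phase gradient analysis (DPGA): local shear-wavenumber maps.

Within a small window, a single harmonic plane wave exp(j*2*pi*(kx*x + ky*y))
has the spatial autocorrelation exp(-j*2*pi*(kx*dx + ky*dy)); the gradient of
its phase at zero lag gives (kx, ky) directly and k = sqrt(kx^2 + ky^2),
without fitting. Superposed waves travelling in different directions break the
single-wave assumption (two opposite waves make a standing field with zero
phase gradient), so the field is first split by a bank of one-sided Gaussian
directional filters in the lateral spatial-frequency plane, the gradient is
evaluated per direction, low-displacement directions are masked against the
air noise floor, and the surviving directions are averaged.

Speed and modulus follow as c = f0/k and G = rho*c^2 (homogeneous isotropic
surface-wave assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.fft import fft2, ifft2
from scipy.ndimage import gaussian_filter
from scipy.signal import resample

from .wavefield import DisplacementVolume

__all__ = [
    "DirectionalFilterBank",
    "WindowSpec",
    "KMap",
    "build_filter_bank",
    "apply_filters",
    "windowed_autocorrelation",
    "windowed_autocorrelation_direct",
    "phase_gradient_k",
    "snr_mask",
    "aggregate_directions",
    "k_to_speed_modulus",
    "dpga_map",
    "conventional_pg",
    "surface_slab_average",
    "downsample_field",
    "analyze_volume",
]


@dataclass(frozen=True)
class DirectionalFilterBank:
    """One-sided Gaussian angular filters over the lateral frequency plane.

    Filter d passes spatial frequencies whose azimuth lies within half a turn
    of its center angle, with Gaussian weight exp(-dtheta^2/(2*sigma_theta^2));
    the opposing half-plane and the DC bin are hard-zeroed, so each filter
    selects a single propagation direction, not a line of propagation.
    """

    angles: np.ndarray
    sigma_theta: float
    gains: np.ndarray  # (n_dirs, nx, ny), FFT bin order

    @property
    def n_dirs(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class WindowSpec:
    """Square autocorrelation window: edge w pixels, non-overlapping tiling.

    zero_pad_factor >= 2 makes the FFT-path autocorrelation linear rather
    than circular — in a 2x2 window circular lag 1 would alias lags +1/-1
    and corrupt the phase.
    """

    w: int = 2
    stride: int | None = None
    zero_pad_factor: int = 2

    def __post_init__(self):
        if self.w < 2:
            raise ValueError("window edge must be >= 2 pixels")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.zero_pad_factor < 2:
            raise ValueError("zero_pad_factor must be >= 2 for linear autocorrelation")

    @property
    def step(self) -> int:
        return self.stride if self.stride is not None else self.w


@dataclass
class KMap:
    """Per-window wavenumber estimates and derived maps.

    k is the direction-aggregated magnitude map (cycles/m, NaN = no surviving
    direction); kx/ky are the signed components of the conventional
    (single-path) estimate when available. c (m/s) and G (Pa) are filled when
    f0 and rho are known.
    """

    k: np.ndarray
    kx: np.ndarray | None = None
    ky: np.ndarray | None = None
    k_stack: np.ndarray | None = None  # (n_dirs, nwx, nwy)
    mask: np.ndarray | None = None
    c: np.ndarray | None = None
    G: np.ndarray | None = None
    window_x: np.ndarray | None = None
    window_y: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def median_k(self, region: np.ndarray | None = None) -> float:
        """Median of defined k values, optionally restricted to a boolean region."""
        k = self.k if region is None else np.where(region, self.k, np.nan)
        return float(np.nanmedian(k))


# ---------------------------------------------------------------------------
# directional filtering
# ---------------------------------------------------------------------------


def build_filter_bank(
    shape: tuple,
    dx: float,
    dy: float,
    n_dirs: int = 32,
    sigma_theta: float | None = None,
) -> DirectionalFilterBank:
    """Build the directional filter bank for fields of the given (nx, ny) shape."""
    if n_dirs < 4:
        raise ValueError("need at least 4 directions")
    if sigma_theta is None:
        sigma_theta = 2 * np.pi / n_dirs
    if sigma_theta <= 0:
        raise ValueError("sigma_theta must be positive")
    nx, ny = shape
    kx = np.fft.fftfreq(nx, d=dx)[:, None]
    ky = np.fft.fftfreq(ny, d=dy)[None, :]
    theta = np.arctan2(np.broadcast_to(ky, (nx, ny)), np.broadcast_to(kx, (nx, ny)))
    angles = 2 * np.pi * np.arange(n_dirs) / n_dirs
    gains = np.empty((n_dirs, nx, ny))
    for d, th_d in enumerate(angles):
        dth = np.angle(np.exp(1j * (theta - th_d)))
        g = np.exp(-(dth**2) / (2 * sigma_theta**2))
        g[np.abs(dth) >= np.pi / 2] = 0.0  # one-sided: kill the opposing half-plane
        g[0, 0] = 0.0  # no DC
        gains[d] = g
    return DirectionalFilterBank(angles=angles, sigma_theta=float(sigma_theta), gains=gains)


def apply_filters(enface_field: np.ndarray, bank: DirectionalFilterBank) -> np.ndarray:
    """Split a 2D complex field into per-direction travelling-wave fields."""
    f = np.asarray(enface_field)
    if f.ndim != 2:
        raise ValueError("expected a 2D en-face field")
    if f.shape != bank.gains.shape[1:]:
        raise ValueError(f"field shape {f.shape} does not match bank {bank.gains.shape[1:]}")
    F = fft2(f)
    return ifft2(F[None, :, :] * bank.gains, axes=(-2, -1))


# ---------------------------------------------------------------------------
# windowed autocorrelation
# ---------------------------------------------------------------------------


def _tile_windows(field: np.ndarray, w: int, step: int) -> np.ndarray:
    """(nwx, nwy, w, w) view of non-overlapping (or strided) windows."""
    nx, ny = field.shape
    if w > nx or w > ny:
        raise ValueError(f"window {w} larger than field {field.shape}")
    x0 = np.arange(0, nx - w + 1, step)
    y0 = np.arange(0, ny - w + 1, step)
    out = np.empty((len(x0), len(y0), w, w), dtype=field.dtype)
    for i, xs in enumerate(x0):
        for j, ys in enumerate(y0):
            out[i, j] = field[xs : xs + w, ys : ys + w]
    return out


def windowed_autocorrelation(field: np.ndarray, win: WindowSpec | None = None) -> dict:
    """Linear 2D autocorrelation of each window via the FFT path.

    Per window: zero-pad to zero_pad_factor*w, FFT2, squared magnitude,
    inverse FFT2. Returned lags follow the convention
    AC(d) = sum_n f[n] * conj(f[n + d]), so a pure exponential
    exp(j*2*pi*kx*x) gives arg AC(+1, 0) = -2*pi*kx*dx. The zero-lag value is
    the window energy (real up to rounding).

    Returns a dict with ``ac`` (nwx, nwy, P, P) centered lags, ``center`` the
    zero-lag index, and the window tiling geometry.
    """
    win = win or WindowSpec()
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("expected a 2D field")
    wins = _tile_windows(field, win.w, win.step)
    P = win.zero_pad_factor * win.w
    padded = np.zeros(wins.shape[:2] + (P, P), dtype=complex)
    padded[:, :, : win.w, : win.w] = wins
    F = fft2(padded, axes=(-2, -1))
    ac = np.conj(ifft2(np.abs(F) ** 2, axes=(-2, -1)))
    ac = np.fft.fftshift(ac, axes=(-2, -1))
    return {"ac": ac, "center": P // 2, "w": win.w, "step": win.step}


def windowed_autocorrelation_direct(field: np.ndarray, win: WindowSpec | None = None) -> dict:
    """Brute-force lag-sum autocorrelation (independent oracle for the FFT path).

    AC(dx, dy) = sum over valid n of f[n] * conj(f[n + d]); O(w^4) per window.
    """
    win = win or WindowSpec()
    wins = _tile_windows(np.asarray(field), win.w, win.step)
    w = win.w
    P = win.zero_pad_factor * w
    c = P // 2
    ac = np.zeros(wins.shape[:2] + (P, P), dtype=complex)
    for ddx in range(-(w - 1), w):
        for ddy in range(-(w - 1), w):
            xs = slice(max(0, -ddx), min(w, w - ddx))
            ys = slice(max(0, -ddy), min(w, w - ddy))
            xs2 = slice(xs.start + ddx, xs.stop + ddx)
            ys2 = slice(ys.start + ddy, ys.stop + ddy)
            ac[:, :, c + ddx, c + ddy] = np.sum(
                wins[:, :, xs, ys] * np.conj(wins[:, :, xs2, ys2]), axis=(-2, -1)
            )
    return {"ac": ac, "center": c, "w": w, "step": win.step}


def phase_gradient_k(ac: dict, dx: float, dy: float) -> tuple:
    """(kx, ky, k) per window from the lag-1 autocorrelation phase.

    kx = -arg AC(+1, 0) / (2*pi*dx) and likewise for ky; exact for a pure
    exponential, which is what directional filtering enforces. Windows with a
    vanishing autocorrelation at the needed lag are returned as NaN (masked
    downstream), not raised.
    """
    A = ac["ac"]
    c = ac["center"]
    a10 = A[..., c + 1, c]
    a01 = A[..., c, c + 1]
    e0 = np.abs(A[..., c, c])
    tiny = np.finfo(float).tiny
    bad = (np.abs(a10) <= 1e-12 * (e0 + tiny)) | (np.abs(a01) <= 1e-12 * (e0 + tiny))
    kx = -np.angle(a10) / (2 * np.pi * dx)
    ky = -np.angle(a01) / (2 * np.pi * dy)
    kx = np.where(bad, np.nan, kx)
    ky = np.where(bad, np.nan, ky)
    k = np.hypot(kx, ky)
    return kx, ky, k


# ---------------------------------------------------------------------------
# masking, aggregation, conversion
# ---------------------------------------------------------------------------


def snr_mask(
    field: np.ndarray,
    air_rows: slice,
    win: WindowSpec | None = None,
    threshold: float = 2.0,
    *,
    air_rms: float | None = None,
) -> np.ndarray:
    """Boolean keep-mask per window: window RMS / air RMS >= threshold.

    The air region (noise-only y-locations) is the displacement noise floor;
    windows whose RMS displacement does not clear ``threshold`` times it are
    dropped. A precomputed ``air_rms`` (e.g. scaled for a filtered branch)
    overrides the in-field air estimate.
    """
    win = win or WindowSpec()
    field = np.asarray(field)
    if air_rms is None:
        air = field[:, air_rows]
        if air.size == 0:
            raise ValueError("air region is empty")
        air_rms = float(np.sqrt(np.mean(np.abs(air) ** 2)))
    wins = _tile_windows(field, win.w, win.step)
    win_rms = np.sqrt(np.mean(np.abs(wins) ** 2, axis=(-2, -1)))
    if air_rms == 0:
        return np.ones(win_rms.shape, dtype=bool)
    return win_rms / air_rms >= threshold


def aggregate_directions(
    k_stack: np.ndarray,
    mask: np.ndarray,
    mode: str = "uniform",
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Average per-direction k over surviving directions.

    mode="uniform": plain mean; mode="energy": weighted by the per-direction
    window energy (zero-lag autocorrelation). Windows with no surviving
    direction come out NaN.
    """
    if mode not in ("uniform", "energy"):
        raise ValueError("mode must be 'uniform' or 'energy'")
    valid = mask & np.isfinite(k_stack)
    k = np.where(valid, k_stack, np.nan)
    if mode == "uniform":
        num = np.nansum(np.where(valid, k_stack, 0.0), axis=0)
        den = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        return np.where(den > 0, out, np.nan)
    if weights is None:
        raise ValueError("energy mode requires weights")
    wgt = np.where(np.isfinite(k), weights, 0.0)
    num = np.nansum(k * wgt, axis=0)
    den = np.sum(wgt, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def k_to_speed_modulus(k, f0_hz: float, rho_kg_m3: float = 1000.0):
    """(c, G) from wavenumber: c = f0/k (m/s), G = rho*c^2 (Pa). k=0 -> NaN."""
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k > 0, f0_hz / k, np.nan)
    G = rho_kg_m3 * c**2
    return c, G


# ---------------------------------------------------------------------------
# pipelines over en-face fields
# ---------------------------------------------------------------------------


def _window_centers(n: int, w: int, step: int, pitch: float) -> np.ndarray:
    starts = np.arange(0, n - w + 1, step)
    return (starts + (w - 1) / 2 + 0.5) * pitch


def _crop(a: np.ndarray, edge: int) -> np.ndarray:
    if edge <= 0:
        return a
    sl = (Ellipsis, slice(edge, a.shape[-2] - edge), slice(edge, a.shape[-1] - edge))
    return a[sl]


def dpga_map(
    enface_field: np.ndarray,
    dx: float,
    dy: float,
    *,
    n_dirs: int = 32,
    sigma_theta: float | None = None,
    win: WindowSpec | None = None,
    air_rows: slice | None = None,
    snr_threshold: float = 2.0,
    rel_energy: float = 0.1,
    agg_mode: str = "uniform",
    f0_hz: float | None = None,
    rho_kg_m3: float = 1000.0,
    edge_crop: int = 1,
) -> KMap:
    """Full DPGA on one en-face complex field.

    Directional filtering -> per-direction windowed autocorrelation -> lag-1
    phase gradient -> per-direction SNR masking -> direction average. One ring
    of edge windows is cropped by default (edge artifacts from the full-length
    FFTs), which turns the 37x37 tiling of a 75x75 field into the 35x35 map
    used for reporting.

    Besides the air-floor SNR mask, a direction is kept in a window only if
    its energy reaches ``rel_energy`` of the window's dominant direction:
    spectral-leakage tails of strong waves masquerade as weak waves in other
    directions and would otherwise dilute the average (set 0 to disable).
    """
    win = win or WindowSpec()
    field = np.asarray(enface_field)

    # The air strip is the noise floor, not part of the analyzed field: a
    # zeroed strip inside the transform would leak energy into every
    # directional branch. Filter the signal region only; the white-noise
    # floor of branch d is the raw air RMS times the filter's RMS gain.
    air_sigma = None
    if air_rows is not None:
        air = field[:, air_rows]
        if air.size == 0:
            raise ValueError("air region is empty")
        air_sigma = float(np.sqrt(np.mean(np.abs(air) ** 2)))
        field = field[:, : air_rows.start]

    bank = build_filter_bank(field.shape, dx, dy, n_dirs=n_dirs, sigma_theta=sigma_theta)
    branches = apply_filters(field, bank)
    branch_gain = np.sqrt(np.mean(bank.gains**2, axis=(1, 2)))

    k_list, e_list, m_list = [], [], []
    for d in range(bank.n_dirs):
        ac = windowed_autocorrelation(branches[d], win)
        _, _, k_d = phase_gradient_k(ac, dx, dy)
        energy = np.abs(ac["ac"][..., ac["center"], ac["center"]])
        if air_sigma is not None:
            m_d = snr_mask(
                branches[d], air_rows, win, snr_threshold,
                air_rms=air_sigma * float(branch_gain[d]),
            )
        else:
            m_d = np.ones_like(k_d, dtype=bool)
        k_list.append(k_d)
        e_list.append(energy)
        m_list.append(m_d)
    k_stack = np.stack(k_list)
    energies = np.stack(e_list)
    mask = np.stack(m_list)
    if rel_energy > 0:
        mask = mask & (energies >= rel_energy * energies.max(axis=0, keepdims=True))

    k_agg = aggregate_directions(k_stack, mask, agg_mode, weights=energies)

    k_agg = _crop(k_agg, edge_crop)
    k_stack = _crop(k_stack, edge_crop)
    mask = _crop(mask, edge_crop)

    wx = _window_centers(field.shape[0], win.w, win.step, dx)
    wy = _window_centers(field.shape[1], win.w, win.step, dy)
    if edge_crop > 0:
        wx = wx[edge_crop:-edge_crop]
        wy = wy[edge_crop:-edge_crop]

    c = G = None
    if f0_hz is not None:
        c, G = k_to_speed_modulus(k_agg, f0_hz, rho_kg_m3)
    return KMap(
        k=k_agg,
        k_stack=k_stack,
        mask=mask,
        c=c,
        G=G,
        window_x=wx,
        window_y=wy,
        meta={"method": "dpga", "n_dirs": n_dirs, "agg_mode": agg_mode, "w": win.w, "edge_crop": edge_crop},
    )


def _smooth_nan(a: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs (normalized convolution)."""
    if sigma <= 0:
        return a
    valid = np.isfinite(a)
    filled = np.where(valid, a, 0.0)
    num = gaussian_filter(filled, sigma)
    den = gaussian_filter(valid.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-12] = np.nan
    return out


def conventional_pg(
    enface_field: np.ndarray,
    dx: float,
    dy: float,
    *,
    win: WindowSpec | None = None,
    smooth_sigma_px: float = 2.0,
    air_rows: slice | None = None,
    snr_threshold: float = 2.0,
    f0_hz: float | None = None,
    rho_kg_m3: float = 1000.0,
    edge_crop: int = 1,
) -> KMap:
    """Phase-gradient wavenumber map without directional filtering.

    Identical windowing and lag-1 gradient, applied to the raw complex field,
    followed by Gaussian smoothing of the k map (sigma = 2 windows by default,
    FWHM ~5). Opposite-travelling waves interfere destructively in the phase
    gradient here — the failure mode directional filtering exists to fix.
    """
    win = win or WindowSpec()
    field = np.asarray(enface_field)
    ac = windowed_autocorrelation(field, win)
    kx, ky, k = phase_gradient_k(ac, dx, dy)
    if air_rows is not None:
        keep = snr_mask(field, air_rows, win, snr_threshold)
        k = np.where(keep, k, np.nan)
        kx = np.where(keep, kx, np.nan)
        ky = np.where(keep, ky, np.nan)
    k = _smooth_nan(k, smooth_sigma_px)
    k, kx, ky = _crop(k, edge_crop), _crop(kx, edge_crop), _crop(ky, edge_crop)
    wx = _window_centers(field.shape[0], win.w, win.step, dx)
    wy = _window_centers(field.shape[1], win.w, win.step, dy)
    if edge_crop > 0:
        wx = wx[edge_crop:-edge_crop]
        wy = wy[edge_crop:-edge_crop]
    c = G = None
    if f0_hz is not None:
        c, G = k_to_speed_modulus(k, f0_hz, rho_kg_m3)
    return KMap(
        k=k, kx=kx, ky=ky, c=c, G=G, window_x=wx, window_y=wy,
        meta={"method": "conventional", "smooth_sigma_px": smooth_sigma_px, "w": win.w, "edge_crop": edge_crop},
    )


def surface_slab_average(vol: DisplacementVolume, depth_m: float = 20e-6, thickness_slices: int | None = None) -> np.ndarray:
    """Complex mean over a shallow z-slab below the (flat) surface.

    Surface waves are analyzed in a slab starting ``depth_m`` below z=0;
    averaging depth-decorrelated noise improves displacement SNR by about
    sqrt(n_slices).
    """
    nz = vol.S.shape[0]
    z0 = int(round(depth_m / vol.dz)) if vol.dz > 0 else 0
    if z0 >= nz:
        if nz == 1:
            z0 = 0  # single-slice volume: the slab is that slice
        else:
            raise ValueError("slab depth outside volume")
    n = thickness_slices if thickness_slices is not None else nz - z0
    if n < 1 or z0 + n > nz:
        raise ValueError("slab outside volume")
    return vol.S[z0 : z0 + n].mean(axis=0)


def downsample_field(field: np.ndarray, n_out: int, axis: int = 0) -> np.ndarray:
    """Band-limited Fourier resampling along one axis (anti-aliased decimation)."""
    field = np.asarray(field)
    if n_out == field.shape[axis]:
        return field
    return resample(field, n_out, axis=axis)


def analyze_volume(
    vol: DisplacementVolume,
    *,
    method: str = "dpga",
    depth_m: float = 20e-6,
    thickness_slices: int | None = None,
    n_lateral: int | None = None,
    **kwargs,
) -> KMap:
    """Slab-average a coherent volume, square the lateral grid, run a k-map method.

    The x dimension (finely sampled for demodulation) is decimated to match
    the y dimension (75 by default), then ``dpga_map`` or ``conventional_pg``
    runs on the en-face field. Air rows propagate into the SNR mask.
    """
    if vol.stage != "coherent":
        raise ValueError(f"analyze_volume expects a coherent volume, got stage={vol.stage!r}")
    enface = surface_slab_average(vol, depth_m, thickness_slices)
    ny = vol.S.shape[2]
    n_out = n_lateral or ny
    field = downsample_field(enface, n_out, axis=0)
    dx_dec = vol.protocol.range_x_m / n_out
    air = vol.air_rows
    kwargs.setdefault("f0_hz", vol.protocol.f0_hz)
    if method == "dpga":
        return dpga_map(field, dx_dec, vol.dy, air_rows=air, **kwargs)
    if method == "conventional":
        return conventional_pg(field, dx_dec, vol.dy, air_rows=air, **kwargs)
    raise ValueError("method must be 'dpga' or 'conventional'")
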