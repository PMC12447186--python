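"""Coherent shear-wave field recovery from raster-scanned displacement data.

Raster scanning turns the harmonic time factor exp(-j*2*pi*f0*t) into an
in-plane amplitude modulation at carrier f_c = f0/v_scan. Recovery:

1. (optional) least-squares 2D phase unwrapping of wrapped Doppler phase;
2. in-plane demodulation: per-A-line multiplication by exp(+j*2*pi*nx*f0/f_A),
   which by the DFT shift property moves the negative-carrier copy of the
   spectrum to DC without requiring an integer pixel shift;
3. a Blackman band-pass centered at DC along x, suppressing noise and the
   mirror copy of the signal at the opposite carrier;
4. out-of-plane alignment: y-location ny was acquired delta_t_y later per
   step, so it is propagated back by ny*delta_t_y, removing the artifactual
   phase jumps between y-locations; then a Blackman low-pass along y.

The result is a spatially and temporally coherent complex volume: its real
part is a snapshot of the displacement field, and multiplying by a unit phasor
propagates the whole field in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn, fft, ifft
from scipy.signal.windows import blackman

from .protocol import ScanProtocol
from .wavefield import DisplacementVolume

__all__ = [
    "RecoveryConfig",
    "default_bandpass_width",
    "unwrap_phase_2d",
    "demodulate_inplane",
    "bandpass_dc",
    "align_y",
    "propagate_time",
    "snapshot",
    "recover_volume",
]


def default_bandpass_width(f0_hz: float) -> int:
    """Band-pass width in spectral pixels: 25 at 1 kHz, 33 at 2 kHz.

    Higher excitation frequencies carry larger shear wavenumbers and thus
    wider spatial-frequency support around the carrier.
    """
    return 25 if f0_hz <= 1500.0 else 33


@dataclass(frozen=True)
class RecoveryConfig:
    """Knobs of the recovery chain.

    bandpass_width : spectral pixels of the Blackman band-pass at DC
        (None = choose from f0: 25 at 1 kHz, 33 at 2 kHz).
    carrier_sign : which carrier copy the demodulation centers at DC.
        "negative" (default) keeps the exp(-j*2*pi*f0*t) analytic copy, for
        which forward time propagation is exp(-j*2*pi*f0*dt).
    y_lowpass : apply the Blackman low-pass along y (length n_y).
    """

    bandpass_width: int | None = None
    bandpass_window: str = "blackman"
    carrier_sign: str = "negative"
    y_lowpass: bool = True

    def __post_init__(self):
        if self.carrier_sign not in ("negative", "positive"):
            raise ValueError("carrier_sign must be 'negative' or 'positive'")
        if self.bandpass_window != "blackman":
            raise ValueError("only the Blackman taper is supported")

    @property
    def propagate_sign(self) -> int:
        """Sign of the forward-time phasor exp(sign*j*2*pi*f0*dt)."""
        return -1 if self.carrier_sign == "negative" else +1


# ---------------------------------------------------------------------------
# 2D least-squares phase unwrapping (discrete Poisson / DCT diagonalization)
# ---------------------------------------------------------------------------


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def unwrap_phase_2d(wrapped: np.ndarray) -> np.ndarray:
    """Unweighted least-squares 2D phase unwrapping.

    Solves the discrete Poisson equation whose source term is the divergence
    of the wrapped phase differences, diagonalized by the type-II cosine
    transform (Neumann boundaries). The result is defined up to an additive
    constant; residue-free inputs are recovered exactly, noisy ones in the
    least-squares sense.
    """
    w = np.asarray(wrapped, dtype=float)
    if w.ndim != 2:
        raise ValueError("expected a 2D phase map")
    if not np.all(np.isfinite(w)):
        raise ValueError("phase map contains non-finite values")
    m, n = w.shape
    if m == 1 and n == 1:
        return w.copy()

    dx = _wrap(np.diff(w, axis=0))
    dy = _wrap(np.diff(w, axis=1))
    rho = np.zeros_like(w)
    rho[:-1, :] += dx
    rho[1:, :] -= dx
    rho[:, :-1] += dy
    rho[:, 1:] -= dy

    d = dctn(rho, norm="ortho")
    i = np.arange(m)[:, None]
    j = np.arange(n)[None, :]
    denom = 2.0 * (np.cos(np.pi * i / m) + np.cos(np.pi * j / n) - 2.0)
    denom[0, 0] = 1.0
    phi = d / denom
    phi[0, 0] = 0.0
    return idctn(phi, norm="ortho")


# ---------------------------------------------------------------------------
# in-plane demodulation and band-pass
# ---------------------------------------------------------------------------


def demodulate_inplane(
    S0: np.ndarray,
    protocol: ScanProtocol,
    *,
    carrier_sign: str = "negative",
    x_axis: int = -2,
) -> np.ndarray:
    """Remove the scan-induced carrier by a spatial-domain phase ramp.

    Multiplies retained A-line nx by exp(+j*2*pi*nx*f0/f_A) (negative-carrier
    convention), equivalent to shifting the x spectrum by +delta_k pixels —
    with delta_k allowed to be non-integer. Per-pixel magnitude is preserved
    exactly.
    """
    S0 = np.asarray(S0)
    nf = S0.shape[x_axis]
    if nf != protocol.n_f:
        raise ValueError(f"x axis has {nf} samples, protocol expects n_f={protocol.n_f}")
    sign = +1 if carrier_sign == "negative" else -1
    nx = np.arange(nf)
    ramp = np.exp(sign * 1j * 2 * np.pi * nx * protocol.f0_hz / protocol.f_a_hz)
    shape = [1] * S0.ndim
    shape[x_axis] = nf
    return S0 * ramp.reshape(shape)


def _dc_taper(n: int, width: int) -> np.ndarray:
    """Blackman taper of `width` bins centered on the DC bin, FFT bin order."""
    if not 1 <= width <= n:
        raise ValueError(f"band-pass width {width} out of range [1, {n}]")
    taper = np.zeros(n)
    win = blackman(width, sym=True)
    offs = np.arange(width) - width // 2
    taper[offs % n] = win
    taper[0] = win[width // 2]  # exact unit gain at DC for odd widths
    return taper


def bandpass_dc(field: np.ndarray, width: int, *, x_axis: int = -2) -> np.ndarray:
    """Blackman band-pass centered at DC along the x (fast-scan) axis.

    FFT along x, multiply by a Blackman taper of `width` spectral pixels
    centered on the zero-frequency bin (zero outside), inverse FFT. After
    demodulation this keeps the wanted carrier copy and rejects the mirror
    copy two carrier shifts away, plus out-of-band noise.
    """
    field = np.asarray(field)
    n = field.shape[x_axis]
    taper = _dc_taper(n, width)
    shape = [1] * field.ndim
    shape[x_axis] = n
    F = fft(field, axis=x_axis)
    return ifft(F * taper.reshape(shape), axis=x_axis)


# ---------------------------------------------------------------------------
# out-of-plane alignment and time propagation
# ---------------------------------------------------------------------------


def propagate_time(field: np.ndarray, dt: float, f0_hz: float, sign: int = -1) -> np.ndarray:
    """Advance the coherent field by dt seconds: field * exp(sign*j*2*pi*f0*dt).

    sign=-1 matches the negative-carrier convention (the recovered analytic
    signal carries exp(-j*2*pi*f0*t)). Magnitude is preserved exactly.
    """
    return field * np.exp(sign * 1j * 2 * np.pi * f0_hz * dt)


def snapshot(field: np.ndarray, phi: float = 0.0) -> np.ndarray:
    """Real displacement snapshot at phase offset phi: Re(field * exp(j*phi))."""
    return np.real(field * np.exp(1j * phi))


def align_y(
    fields: np.ndarray,
    protocol: ScanProtocol,
    config: RecoveryConfig | None = None,
    *,
    y_axis: int = -1,
) -> np.ndarray:
    """Align y-locations into one coherent volume.

    y-location ny was acquired ny*delta_t_y after the first, so its recovered
    field is propagated back in time by that delay (a linear phase ramp along
    y whose slope is the expected per-step phase delay). A Blackman low-pass
    equal in length to the number of y-locations then suppresses residual
    noise along y.
    """
    config = config or RecoveryConfig()
    fields = np.asarray(fields)
    ny = fields.shape[y_axis]
    if ny != protocol.n_y:
        raise ValueError(f"y axis has {ny} fields, protocol expects n_y={protocol.n_y}")

    iy = np.arange(ny)
    ramp = np.exp(-config.propagate_sign * 1j * 2 * np.pi * protocol.f0_hz * iy * protocol.delta_t_y)
    shape = [1] * fields.ndim
    shape[y_axis] = ny
    out = fields * ramp.reshape(shape)

    if config.y_lowpass and ny > 1:
        win = np.fft.ifftshift(blackman(ny, sym=True))
        F = fft(out, axis=y_axis)
        out = ifft(F * win.reshape(shape), axis=y_axis)
    return out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def recover_volume(vol: DisplacementVolume, config: RecoveryConfig | None = None) -> DisplacementVolume:
    """Run the full recovery chain on a raw raster-scanned volume.

    Unwraps wrapped Doppler phase if the volume was acquired with wrapping,
    demodulates the scan carrier in-plane, band-passes at DC along x, and
    aligns the y-locations. Returns a volume tagged ``stage="coherent"``.
    """
    if vol.stage != "raw":
        raise ValueError(f"recover_volume expects a raw volume, got stage={vol.stage!r}")
    config = config or RecoveryConfig()
    p = vol.protocol
    S = vol.S

    if vol.wrap_scale is not None:
        unwrapped = np.empty_like(S, dtype=float)
        for iy in range(S.shape[2]):
            unwrapped[:, :, iy] = unwrap_phase_2d(S[:, :, iy].real)
        S = (unwrapped / vol.wrap_scale).astype(complex)

    S = demodulate_inplane(S, p, carrier_sign=config.carrier_sign, x_axis=1)
    width = config.bandpass_width or default_bandpass_width(p.f0_hz)
    S = bandpass_dc(S, width, x_axis=1)
    S = align_y(S, p, config, y_axis=2)

    return DisplacementVolume(
        S=S,
        dz=vol.dz,
        dx=vol.dx,
        dy=vol.dy,
        acquisition_time=vol.acquisition_time,
        protocol=p,
        air_rows=vol.air_rows,
        truth=vol.truth,
        stage="coherent",
        wrap_scale=None,
        meta={**vol.meta, "bandpass_width": width, "carrier_sign": config.carrier_sign},
    )
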