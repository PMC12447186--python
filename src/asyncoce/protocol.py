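"""Raster-scan acquisition protocol and its closed-form timing arithmetic.

The OCT beam raster-scans the sample: a B-scan is a sweep of ``n_x`` A-lines
along x (the first ``n_flyback`` of which are scanner flyback and carry no
usable signal), repeated ``n_b`` times per y-location, at ``n_y`` y-locations.
During harmonic shear-wave excitation at ``f0_hz`` this lateral beam motion
amplitude-modulates the displacement field with a spatial carrier

    f_c = f0 / v_scan = f0 * N_f / (f_A * R_x)   [cycles/m]

whose position in the x spectrum, in spectral pixels, is

    dk_px = f_c / dk = f0 * N_f / f_A,   dk = 1/R_x.

All quantities are SI internally (Hz, m, s); flyback A-lines are cropped from
spatial processing but always count toward elapsed time.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = [
    "ScanProtocol",
    "ProtocolError",
    "benchtop_protocol",
    "derive_demodulation",
    "y_step_delay",
    "acquisition_duration",
    "alines_per_period",
    "rate_discrepancy",
]


class ProtocolError(ValueError):
    """An acquisition-protocol invariant is violated."""


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition-timing parameters of one raster-scanned volume.

    Parameters
    ----------
    f_a_hz : float
        A-line (wavelength-sweep) rate, Hz.
    n_x : int
        Raw A-lines per B-scan, including flyback.
    n_flyback : int
        Flyback A-lines cropped from the start of each B-scan.
    n_b : int
        Repeat B-scans per y-location (2 for a Doppler pair).
    n_y : int
        Number of y-locations.
    range_x_m, range_y_m : float
        Lateral scan ranges, m.
    f0_hz : float
        Shear-wave excitation frequency, Hz (0 = no excitation).
    """

    f_a_hz: float
    n_x: int
    n_flyback: int
    n_b: int
    n_y: int
    range_x_m: float
    range_y_m: float
    f0_hz: float

    def __post_init__(self) -> None:
        for name in ("n_x", "n_flyback", "n_b", "n_y"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and not isinstance(v, bool)):
                raise ProtocolError(f"{name} must be an integer, got {v!r}")
        if self.n_x <= 0:
            raise ProtocolError("n_x must be positive")
        if self.n_flyback < 0:
            raise ProtocolError("n_flyback must be non-negative")
        if self.n_f < 1:
            raise ProtocolError("n_f = n_x - n_flyback must be >= 1")
        if self.n_b <= 0:
            raise ProtocolError("n_b must be positive")
        if self.n_y <= 0:
            raise ProtocolError("n_y must be positive")
        if not self.f_a_hz > 0:
            raise ProtocolError("f_a_hz must be positive")
        if self.f0_hz < 0:
            raise ProtocolError("f0_hz must be non-negative")
        if not self.range_x_m > 0:
            raise ProtocolError("range_x_m must be positive")
        if not self.range_y_m > 0:
            raise ProtocolError("range_y_m must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n_f(self) -> int:
        """Retained A-lines per B-scan after flyback cropping."""
        return self.n_x - self.n_flyback

    @property
    def v_scan(self) -> float:
        """In-plane raster scanning speed, m/s (over the retained sweep)."""
        return self.f_a_hz * self.range_x_m / self.n_f

    @property
    def f_c(self) -> float:
        """Scan-induced carrier spatial frequency, cycles/m."""
        return self.f0_hz / self.v_scan

    @property
    def dk(self) -> float:
        """Spectral pixel pitch of the retained x spectrum, cycles/m."""
        return 1.0 / self.range_x_m

    @property
    def delta_k(self) -> float:
        """Carrier position in spectral pixels (real-valued, not rounded)."""
        return self.f0_hz * self.n_f / self.f_a_hz

    @property
    def delta_t_y(self) -> float:
        """Elapsed time between consecutive y-locations, s (raw n_x counts)."""
        return self.n_b * self.n_x / self.f_a_hz

    @property
    def dx(self) -> float:
        """Lateral pixel pitch along x over the retained A-lines, m."""
        return self.range_x_m / self.n_f

    @property
    def dy(self) -> float:
        """Lateral pitch between y-locations, m."""
        return self.range_y_m / self.n_y

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """Flat mapping with the documented key names."""
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        keys = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        missing = keys - set(d)
        if missing:
            raise ProtocolError(f"protocol mapping missing keys: {sorted(missing)}")
        kwargs = {k: d[k] for k in keys}
        for name in ("n_x", "n_flyback", "n_b", "n_y"):
            kwargs[name] = int(kwargs[name])
        for name in ("f_a_hz", "range_x_m", "range_y_m", "f0_hz"):
            kwargs[name] = float(kwargs[name])
        return cls(**kwargs)


def benchtop_protocol(f0_hz: float = 2000.0, *, f_a_hz: float = 100082.0) -> ScanProtocol:
    """The 100-kHz benchtop preset used throughout the examples and tests.

    1536 A-lines per B-scan (first 142 flyback), Doppler B-scan pairs at 75
    y-locations over a 12 x 12 mm field of view, with the directly measured
    A-line rate of 100.082 kHz.
    """
    return ScanProtocol(
        f_a_hz=f_a_hz,
        n_x=1536,
        n_flyback=142,
        n_b=2,
        n_y=75,
        range_x_m=12e-3,
        range_y_m=12e-3,
        f0_hz=f0_hz,
    )


def derive_demodulation(protocol: ScanProtocol) -> dict:
    """Carrier frequency, demodulation pixel shift and scan speed.

    Returns ``{"f_c": cycles/m, "delta_k": spectral pixels, "v_scan": m/s}``.
    ``delta_k`` depends only on the excitation frequency, A-line rate and
    retained A-line count, and is deliberately kept real-valued: demodulation
    happens in the spatial domain, where non-integer shifts are free.
    """
    return {
        "f_c": protocol.f_c,
        "delta_k": protocol.delta_k,
        "v_scan": protocol.v_scan,
    }


def y_step_delay(protocol: ScanProtocol) -> float:
    """Time delay between consecutive y-locations, s: n_b * n_x / f_A."""
    return protocol.delta_t_y


def acquisition_duration(
    mode: str,
    protocol: ScanProtocol | None = None,
    *,
    positions: int | None = None,
    alines_per_position: int | None = None,
    f_a_hz: float | None = None,
) -> float:
    """Total acquisition time, s.

    ``mode="async"`` (raster volume): n_y * n_b * n_x / f_A from `protocol`.
    ``mode="mb"`` (phase-locked MB-mode): positions * alines_per_position / f_A.
    """
    if mode == "async":
        if protocol is None:
            raise ProtocolError("async mode requires a protocol")
        return protocol.n_y * protocol.n_b * protocol.n_x / protocol.f_a_hz
    if mode == "mb":
        if positions is None or alines_per_position is None or f_a_hz is None:
            raise ProtocolError("mb mode requires positions, alines_per_position, f_a_hz")
        if positions <= 0 or alines_per_position <= 0:
            raise ProtocolError("counts must be positive")
        if not f_a_hz > 0:
            raise ProtocolError("f_a_hz must be positive")
        return positions * alines_per_position / f_a_hz
    raise ProtocolError(f"unknown mode {mode!r}; expected 'async' or 'mb'")


def alines_per_period(f_a_hz: float, f0_hz: float) -> float:
    """A-lines acquired per shear-wave period: f_A / f0."""
    if not f0_hz > 0:
        raise ProtocolError("alines_per_period is undefined for f0 = 0")
    if not f_a_hz > 0:
        raise ProtocolError("f_a_hz must be positive")
    return f_a_hz / f0_hz


def rate_discrepancy(alines_total: int, f_a_nominal_hz: float, f_a_true_hz: float) -> float:
    """Accumulated timing error from using a nominal instead of true A-line rate.

    Returns ``alines_total * (1/f_a_nominal - 1/f_a_true)`` in seconds, sign
    preserved. For a full volume this error can reach the scale of a whole
    shear-wave period, which is why the true rate matters for y-alignment.
    """
    if not (f_a_nominal_hz > 0 and f_a_true_hz > 0):
        raise ProtocolError("rates must be positive")
    if alines_total <= 0:
        raise ProtocolError("alines_total must be positive")
    return alines_total * (1.0 / f_a_nominal_hz - 1.0 / f_a_true_hz)
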