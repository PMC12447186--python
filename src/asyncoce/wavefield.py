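"""Ground-truth harmonic shear-wave fields and their raster-scanned acquisition.

The physical model: the particle displacement at position eps and time t is a
superposition of harmonic plane shear waves,

    S(eps, t) = sum_q,l  n_ql * s_ql * exp(j(2*pi*(k * n_q . eps - f0 * t) + phi0)),

with propagation direction n_q, shear polarization n_ql (n_q . n_ql = 0),
amplitude s_ql (m) and wavenumber k (cycles/m). The sensor measures the z
component. Raster scanning samples this field with a per-A-line time that
advances during the B-scan, which turns the temporal oscillation into a
lateral amplitude modulation — the effect the recovery chain demodulates.

Prong-style sources are modeled as surface cylindrical waves with r^(-1/2)
geometric spreading and a straight-ray path-integrated phase through a
(possibly heterogeneous) wavenumber map.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .protocol import ScanProtocol

__all__ = [
    "PlaneWaveComponent",
    "SourceSet",
    "MediumMap",
    "Grid",
    "DisplacementVolume",
    "synthesize_true_field",
    "synthesize_prong_field",
    "heterogeneous_field",
    "isotropic_components",
    "plane_wave_generator",
    "prong_generator",
    "raster_sample",
    "sigma_for_snr",
]

FieldGenerator = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def isotropic_components(
    k: float,
    n_waves: int = 64,
    amplitude_m: float = 100e-9,
    seed: int | None = 0,
) -> list:
    """Equal-k plane waves approximating a fully diffuse (reverberant) ensemble.

    Propagation directions are spread over the 3D sphere on a Fibonacci
    lattice; each wave gets a random shear polarization orthogonal to its
    direction and a random phase. The z-displacement autocorrelation of this
    ensemble follows the spherical-Bessel reverberant model, which is what a
    diffuse-field comparator should be validated against.
    """
    rng = np.random.default_rng(seed)
    i = np.arange(n_waves)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_waves
    r = np.sqrt(1.0 - z**2)
    th = golden * i
    dirs = np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)
    comps = []
    for d in dirs:
        a = rng.standard_normal(3)
        a -= d * (a @ d)
        a /= np.linalg.norm(a)
        comps.append(
            PlaneWaveComponent(
                n_q=tuple(d), n_ql=tuple(a), s_ql=amplitude_m, k=k,
                phi0=float(rng.uniform(0, 2 * np.pi)),
            )
        )
    return comps


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class PlaneWaveComponent:
    """One harmonic plane shear wave.

    n_q : unit propagation direction (x, y, z); n_ql : unit displacement
    polarization, orthogonal to n_q; s_ql : amplitude, m; k : wavenumber,
    cycles/m; phi0 : initial phase, rad.
    """

    n_q: tuple
    n_ql: tuple
    s_ql: float
    k: float
    phi0: float = 0.0

    def __post_init__(self):
        nq = np.asarray(self.n_q, float)
        nl = np.asarray(self.n_ql, float)
        if nq.shape != (3,) or nl.shape != (3,):
            raise ValueError("n_q and n_ql must be 3-vectors")
        if abs(np.linalg.norm(nq) - 1.0) > 1e-8 or abs(np.linalg.norm(nl) - 1.0) > 1e-8:
            raise ValueError("n_q and n_ql must be unit vectors")
        if abs(float(nq @ nl)) > 1e-8:
            raise ValueError("shear polarization requires n_q . n_ql = 0")
        if self.s_ql < 0:
            raise ValueError("amplitude must be non-negative")
        if not self.k > 0:
            raise ValueError("wavenumber must be positive")

    @classmethod
    def inplane(cls, azimuth_rad: float, k: float, s_ql: float, phi0: float = 0.0) -> "PlaneWaveComponent":
        """Laterally propagating, z-polarized wave at the given azimuth."""
        return cls(
            n_q=(float(np.cos(azimuth_rad)), float(np.sin(azimuth_rad)), 0.0),
            n_ql=(0.0, 0.0, 1.0),
            s_ql=s_ql,
            k=k,
            phi0=phi0,
        )


@dataclass(frozen=True)
class SourceSet:
    """Point-contact surface sources evenly spaced on a circle.

    Emulates 1/2/6-prong couplers on a 20-mm-diameter ring: few prongs give a
    near-unidirectional field inside the field of view, many give a diffuse one.
    """

    n_sources: int
    circle_diameter_m: float = 0.020
    center_m: tuple = (0.0, 0.0)
    amplitude_m: float = 100e-9
    per_source_phase_rad: tuple | None = None
    r_min_m: float = 0.5e-3
    angle_offset_rad: float = 0.0

    def __post_init__(self):
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if not self.r_min_m > 0:
            raise ValueError("r_min_m must be positive")
        if self.per_source_phase_rad is not None and len(self.per_source_phase_rad) != self.n_sources:
            raise ValueError("per_source_phase_rad length must equal n_sources")

    @property
    def positions(self) -> np.ndarray:
        """(n_sources, 2) source coordinates, m."""
        ang = self.angle_offset_rad + 2 * np.pi * np.arange(self.n_sources) / self.n_sources
        r = self.circle_diameter_m / 2
        cx, cy = self.center_m
        return np.stack([cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=1)

    @property
    def phases(self) -> np.ndarray:
        if self.per_source_phase_rad is None:
            return np.zeros(self.n_sources)
        return np.asarray(self.per_source_phase_rad, float)


@dataclass(frozen=True)
class MediumMap:
    """Laterally varying shear wavenumber map with an optional soft inclusion.

    k_bg / k_in : background / inclusion wavenumbers, cycles/m (a softer
    inclusion has the larger k). The transition is blended with a logistic
    profile of width ``blend_width_m``; heterogeneity is kinematic only
    (local k along straight rays, no refraction or scattering).
    """

    k_bg: float
    k_in: float | None = None
    inclusion_center_m: tuple = (0.0, 0.0)
    inclusion_radius_m: float = 2.25e-3
    rho_kg_m3: float = 1000.0
    blend_width_m: float = 0.3e-3

    def __post_init__(self):
        if not self.k_bg > 0:
            raise ValueError("k_bg must be positive")
        if self.k_in is not None and not self.k_in > 0:
            raise ValueError("k_in must be positive")
        if self.blend_width_m < 0:
            raise ValueError("blend_width_m must be non-negative")

    @property
    def has_inclusion(self) -> bool:
        return self.k_in is not None and self.k_in != self.k_bg

    def local_k(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Wavenumber at lateral points (x, y), cycles/m."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.k_in is None:
            return np.full(np.broadcast(x, y).shape, self.k_bg)
        cx, cy = self.inclusion_center_m
        d = np.hypot(x - cx, y - cy) - self.inclusion_radius_m  # signed distance
        if self.blend_width_m == 0:
            w = (d < 0).astype(float)
        else:
            # logistic step: ~80% of the transition within blend_width_m
            w = 1.0 / (1.0 + np.exp(d / (self.blend_width_m / 4.0)))
        return self.k_bg + (self.k_in - self.k_bg) * w


@dataclass(frozen=True)
class Grid:
    """Lateral sampling grid: pixel-center coordinates along x and y, m."""

    x: np.ndarray
    y: np.ndarray

    @classmethod
    def from_protocol(cls, p: ScanProtocol) -> "Grid":
        x = (np.arange(p.n_f) + 0.5) * p.dx - p.range_x_m / 2
        y = (np.arange(p.n_y) + 0.5) * p.dy - p.range_y_m / 2
        return cls(x=x, y=y)

    @classmethod
    def regular(cls, nx: int, ny: int, extent_x_m: float, extent_y_m: float | None = None) -> "Grid":
        if extent_y_m is None:
            extent_y_m = extent_x_m
        x = (np.arange(nx) + 0.5) * (extent_x_m / nx) - extent_x_m / 2
        y = (np.arange(ny) + 0.5) * (extent_y_m / ny) - extent_y_m / 2
        return cls(x=x, y=y)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 0.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 0.0

    def mesh(self):
        return np.meshgrid(self.x, self.y, indexing="ij")


@dataclass
class DisplacementVolume:
    """Complex Doppler displacement volume, axis order [z, x, y].

    ``S`` holds the measured displacement (m, complex dtype); x is the fast
    scan axis. ``acquisition_time`` gives the per-(x, y) A-line sample time.
    ``air_rows`` is a slice of noise-only y-locations used as the noise floor
    for SNR masking. ``truth`` optionally keeps the noiseless complex field at
    t = 0 for round-trip validation.
    """

    S: np.ndarray
    dz: float
    dx: float
    dy: float
    acquisition_time: np.ndarray
    protocol: ScanProtocol
    air_rows: slice | None = None
    truth: np.ndarray | None = None
    stage: str = "raw"
    wrap_scale: float | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.S.ndim != 3:
            raise ValueError("S must be 3D [z, x, y]")
        nz, nx, ny = self.S.shape
        if nx != self.protocol.n_f or ny != self.protocol.n_y:
            raise ValueError(
                f"S lateral shape {(nx, ny)} inconsistent with protocol "
                f"(n_f={self.protocol.n_f}, n_y={self.protocol.n_y})"
            )
        if self.acquisition_time.shape != (nx, ny):
            raise ValueError("acquisition_time must have shape (n_f, n_y)")

    @property
    def shape(self):
        return self.S.shape

    def enface(self, iz: int = 0) -> np.ndarray:
        return self.S[iz]

    def signal_y_slice(self) -> slice:
        """y-range excluding the air region."""
        if self.air_rows is None:
            return slice(0, self.S.shape[2])
        return slice(0, self.air_rows.start)


# ---------------------------------------------------------------------------
# field synthesis
# ---------------------------------------------------------------------------


def synthesize_true_field(
    components: Sequence[PlaneWaveComponent],
    grid: Grid,
    t,
    f0_hz: float,
) -> np.ndarray:
    """z-component of the plane-wave superposition on the grid at time t.

    ``t`` may be scalar or an array broadcastable against the (nx, ny) grid,
    which is how raster sampling injects its per-A-line time.
    """
    if len(components) == 0:
        raise ValueError("need at least one plane-wave component")
    X, Y = grid.mesh()
    t = np.asarray(t, float)
    out = np.zeros(np.broadcast(X, t).shape, dtype=complex)
    for c in components:
        nq = np.asarray(c.n_q, float)
        pz = float(np.asarray(c.n_ql, float)[2])
        spatial = c.k * (nq[0] * X + nq[1] * Y)  # eps_z = 0 surface slab
        out += pz * c.s_ql * np.exp(1j * (2 * np.pi * (spatial - f0_hz * t) + c.phi0))
    return out


def _ray_phase_cycles(medium: MediumMap, src_xy, X, Y, n_samples: int = 129) -> np.ndarray:
    """Straight-ray path integral of local k from the source to each point, cycles."""
    sx, sy = src_xy
    if not medium.has_inclusion:
        return medium.k_bg * np.hypot(X - sx, Y - sy)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    r = np.hypot(pts[:, 0] - sx, pts[:, 1] - sy)
    out = np.empty(pts.shape[0])
    # trapezoid along each ray; chunked to bound memory
    s = np.linspace(0.0, 1.0, n_samples)
    chunk = 20000
    for i0 in range(0, pts.shape[0], chunk):
        p = pts[i0 : i0 + chunk]
        xs = sx + np.outer(p[:, 0] - sx, s)
        ys = sy + np.outer(p[:, 1] - sy, s)
        kvals = medium.local_k(xs, ys)
        out[i0 : i0 + chunk] = np.trapezoid(kvals, dx=1.0 / (n_samples - 1), axis=1) * r[i0 : i0 + chunk]
    return out.reshape(X.shape)


def synthesize_prong_field(
    sources: SourceSet,
    medium: MediumMap,
    grid: Grid,
    t,
    f0_hz: float,
) -> np.ndarray:
    """Superposed cylindrical surface waves from the prong sources.

    Each source contributes amplitude * max(r, r_min)^(-1/2) *
    exp(j(2*pi*(path k integral) - 2*pi*f0*t + phi_p)). Amplitudes are scaled
    so the stated source amplitude is reached at the r_min clamp radius.
    """
    X, Y = grid.mesh()
    t = np.asarray(t, float)
    out = np.zeros(np.broadcast(X, t).shape, dtype=complex)
    for (sx, sy), phi_p in zip(sources.positions, sources.phases):
        r = np.hypot(X - sx, Y - sy)
        r_eff = np.maximum(r, sources.r_min_m)
        amp = sources.amplitude_m * np.sqrt(sources.r_min_m / r_eff)
        phase_cyc = _ray_phase_cycles(medium, (sx, sy), X, Y)
        out += amp * np.exp(1j * (2 * np.pi * (phase_cyc - f0_hz * t) + phi_p))
    return out


def heterogeneous_field(
    medium: MediumMap,
    sources: SourceSet,
    grid: Grid,
    t,
    f0_hz: float,
) -> np.ndarray:
    """Prong field through a medium that must contain an inclusion."""
    if medium.k_in is None:
        raise ValueError("heterogeneous_field requires a medium with an inclusion")
    return synthesize_prong_field(sources, medium, grid, t, f0_hz)


def plane_wave_generator(components: Sequence[PlaneWaveComponent], f0_hz: float) -> FieldGenerator:
    """Field generator closure f(X, Y, T) for raster sampling."""
    if len(components) == 0:
        raise ValueError("need at least one plane-wave component")

    comps = [
        (np.asarray(c.n_q, float), float(np.asarray(c.n_ql, float)[2]), c.s_ql, c.k, c.phi0)
        for c in components
    ]

    def gen(X, Y, T):
        out = np.zeros(np.broadcast(X, Y, T).shape, dtype=complex)
        for nq, pz, s, k, phi0 in comps:
            spatial = k * (nq[0] * X + nq[1] * Y)
            out += pz * s * np.exp(1j * (2 * np.pi * (spatial - f0_hz * T) + phi0))
        return out

    return gen


def prong_generator(sources: SourceSet, medium: MediumMap, f0_hz: float) -> FieldGenerator:
    """Prong-source generator closure; the static phase map is cached per grid."""
    cache: dict = {}

    def gen(X, Y, T):
        key = (X.shape, float(X.flat[0]), float(Y.flat[0]), float(X.flat[-1]), float(Y.flat[-1]))
        if key not in cache:
            terms = []
            for (sx, sy), phi_p in zip(sources.positions, sources.phases):
                r = np.hypot(X - sx, Y - sy)
                r_eff = np.maximum(r, sources.r_min_m)
                amp = sources.amplitude_m * np.sqrt(sources.r_min_m / r_eff)
                phase_cyc = _ray_phase_cycles(medium, (sx, sy), X, Y)
                terms.append(amp * np.exp(1j * (2 * np.pi * phase_cyc + phi_p)))
            cache[key] = np.sum(terms, axis=0)
        return cache[key] * np.exp(-1j * 2 * np.pi * f0_hz * np.asarray(T, float))

    return gen


# ---------------------------------------------------------------------------
# raster-scan acquisition
# ---------------------------------------------------------------------------


def sigma_for_snr(signal_rms: float, snr_db: float) -> float:
    """Complex-noise std giving the requested displacement SNR in dB."""
    return signal_rms / (10.0 ** (snr_db / 20.0))


def raster_sample(
    field_generator: FieldGenerator,
    protocol: ScanProtocol,
    grid: Grid | None = None,
    *,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    wrap: bool = False,
    wrap_scale: float | None = None,
    measurement: str = "real",
    air_fraction: float = 0.05,
    n_z: int = 1,
    dz: float = 10e-6,
    swap_axes: bool = False,
) -> DisplacementVolume:
    """Emulate Doppler displacement acquisition of a wave field by raster scan.

    Each retained A-line nx at y-location iy is sampled at

        t(nx, iy) = iy * n_b * n_x / f_A + (n_flyback + nx) / f_A,

    i.e. flyback A-lines count toward elapsed time but are cropped spatially
    (the grid covers retained A-lines only). The measurement is the real part
    of the complex field by default (a Doppler phase-difference displacement
    is real); ``measurement="analytic"`` keeps the complex value for identity
    checks. Circularly-symmetric complex Gaussian noise of total std
    ``noise_sigma`` is added per z-slice (seeded). The last ``air_fraction``
    of y-locations are zeroed to noise only ("air"). With ``wrap=True`` the
    real displacement is converted to Doppler phase with ``wrap_scale`` rad/m
    (default: max |S| maps to 1.5*pi) and wrapped into (-pi, pi].

    ``swap_axes=True`` exchanges the roles of the physical x/y coordinates at
    field evaluation, emulating a fast/slow scan-axis swap on the same scene.
    """
    if measurement not in ("real", "analytic"):
        raise ValueError("measurement must be 'real' or 'analytic'")
    if grid is None:
        grid = Grid.from_protocol(protocol)
    if grid.x.size != protocol.n_f or grid.y.size != protocol.n_y:
        raise ValueError("grid shape inconsistent with protocol (n_f, n_y)")

    p = protocol
    X, Y = grid.mesh()
    nx_idx = np.arange(p.n_f)[:, None]
    iy_idx = np.arange(p.n_y)[None, :]
    T = iy_idx * p.delta_t_y + (p.n_flyback + nx_idx) / p.f_a_hz

    if swap_axes:
        field = field_generator(Y, X, T)
    else:
        field = field_generator(X, Y, T)
    truth = field_generator(Y, X, np.zeros_like(T)) if swap_axes else field_generator(X, Y, np.zeros_like(T))

    if measurement == "real":
        S2d = field.real.astype(complex)
    else:
        S2d = field.astype(complex)

    n_air = max(1, int(round(air_fraction * p.n_y))) if air_fraction > 0 else 0
    air = slice(p.n_y - n_air, p.n_y) if n_air else None

    S = np.broadcast_to(S2d, (n_z,) + S2d.shape).copy()
    if air is not None:
        S[:, :, air] = 0.0

    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        noise = rng.standard_normal(S.shape) + 1j * rng.standard_normal(S.shape)
        S = S + (noise_sigma / np.sqrt(2.0)) * noise

    used_wrap_scale = None
    if wrap:
        peak = float(np.max(np.abs(S.real))) if np.any(S.real) else 1.0
        used_wrap_scale = wrap_scale if wrap_scale is not None else 1.5 * np.pi / peak
        phase = S.real * used_wrap_scale
        wrapped = np.angle(np.exp(1j * phase))
        S = wrapped.astype(complex)

    return DisplacementVolume(
        S=S,
        dz=dz,
        dx=grid.dx,
        dy=grid.dy,
        acquisition_time=T,
        protocol=p,
        air_rows=air,
        truth=truth,
        stage="raw",
        wrap_scale=used_wrap_scale,
        meta={"measurement": measurement, "seed": seed, "noise_sigma": noise_sigma, "swap_axes": swap_axes},
    )
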