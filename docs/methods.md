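# Methods

This note documents the models, numerical choices and limitations behind
`asyncoce`. Units are SI throughout; wavenumbers are in cycles/m (so the
radian-domain argument of any special function carries an explicit 2π).

## Field model and acquisition emulation

The displacement field is a superposition of harmonic plane shear waves: each
component has a unit propagation direction `n_q`, a unit polarization `n_ql`
orthogonal to it (shear constraint), an amplitude in meters, a wavenumber in
cycles/m and an initial phase. The sensor measures the z (optical-axis)
component on the z = 0 surface slab.

Raster sampling evaluates the field at per-A-line times
`t(n_x, i_y) = i_y·N_b·N_x/f_A + (N_fly + n_x)/f_A`: flyback A-lines occupy
the first `N_fly` samples of each B-scan, count toward elapsed time, and are
cropped from space. The default measurement is the **real part** of the
complex field — a Doppler phase-difference displacement is real, and this is
what creates the two carrier copies (at ±f_c) that the band-pass must
separate. An `analytic` option keeps the complex value for algebraic identity
checks; energy conservation under the unit-modulus amplitude modulation holds
exactly in that mode.

Noise is circularly-symmetric complex Gaussian with total standard deviation
σ, seeded through `numpy.random.default_rng`; `sigma_for_snr` converts a
displacement SNR in dB into σ. The last 5% of y-locations are zeroed to noise
only ("air") and serve as the displacement noise floor. Optional phase
wrapping maps the real displacement to Doppler phase with a configurable
scale (default: the peak maps to 1.5π so wraps actually occur) and folds it
into (−π, π].

Prong-style sources are surface cylindrical waves with r^(−1/2) geometric
spreading, clamped at `r_min` (default 0.5 mm) near the source; their phase is
a straight-ray path integral of the local wavenumber map, evaluated by a
129-point trapezoid per ray (chunked, exact for homogeneous media). The
heterogeneous medium is kinematic only: a logistic blend of width 0.3 mm
between background and inclusion wavenumber, no refraction or reflection at
the boundary. This reproduces local-wavelength contrast, which is all the
estimators consume; it deliberately does not model scattering physics.

Default study conditions mirror a benchtop agar phantom setup: 100.082-kHz
A-line rate, 1536 A-lines per B-scan with 142 flyback, Doppler pairs at 75
y-locations over 12×12 mm, shear speeds 3.5 m/s at 1 kHz and 4.5 m/s at
2 kHz excitation, source amplitudes 100 nm, displacement SNR 20 dB, soft
inclusion at 2 m/s with 2.25-mm radius.

### What the simulator does not emulate

Optical speckle, the confocal PSF, depth-dependent signal decay, sample
surface topography (the surface is flat by construction, so no flattening or
surface-wave/refractive-index correction is needed or implemented), bulk
motion, and viscoelastic dispersion. Passing tests therefore demonstrate the
*signal-processing chain* is correct under the stated wave model; they do not
certify performance against those instrument- and tissue-level effects.

## Coherence recovery

- **Phase unwrapping** (used only when the simulated acquisition wrapped the
  Doppler phase): unweighted least-squares 2D unwrapping — the discrete
  Poisson equation assembled from wrapped phase differences, diagonalized by
  the type-II DCT with Neumann boundaries. Exact on residue-free inputs,
  least-squares smoothing on noisy ones; the additive constant is arbitrary.
- **Demodulation**: multiplication by `exp(+j 2π n_x f0/f_A)`, which shifts
  the spectrum by +Δk pixels and centres the negative-carrier copy at DC. Δk
  is kept real-valued; nothing is rounded. Magnitude is preserved per pixel.
- **Band-pass**: a Blackman taper of the stated width (25 px at 1 kHz, 33 px
  at 2 kHz — wider at higher f0 because the shear spatial-frequency support
  scales with k) centred on the DC bin of the retained-A-line spectrum, zero
  elsewhere. The taper shape *is* the pass band; the width is the only knob.
  Since the spectral pixel pitch is 1/R_x regardless of the sample count, the
  width transfers unchanged between the 1536- and 1394-sample readings.
- **Sign pairing**: with the negative-carrier copy at DC, the recovered
  analytic signal carries `exp(−j 2π f0 t)`, so forward time propagation is
  `exp(−j 2π f0 Δt)` and y-alignment *removes* the accumulated acquisition
  delay: `aligned[i_y] = field[i_y] · exp(+j 2π f0 i_y Δt_y)`. The pairing is
  pinned by two tests (crest advance along the propagation direction; 0.95+
  round-trip correlation), not by convention. Choosing the positive carrier
  flips both signs consistently.
- **y low-pass**: Blackman window of length N_y applied across the full
  y spectrum centred at DC. No windowing is applied before the x-FFT; edge
  artifacts are accepted and cropped at the map stage.

## DPGA

The directional filter bank has 32 one-sided Gaussian angular filters,
σ_θ = 2π/32 (one sector spacing — smooth overlap without mixing opposite
directions; the sum of squared gains is azimuth-uniform to ~0.02%). The
opposing half-plane and the DC bin are hard zeros.

Windowed autocorrelation: non-overlapping 2×2-px windows, zero-padded ×2 so
the FFT path (`conj(ifft2(|fft2|²))`) computes the *linear* autocorrelation —
in a 2×2 window a circular lag 1 would alias lags ±1 and corrupt the phase.
The sign convention `AC(d) = Σ f[n]·conj(f[n+d])` makes
`k_x = −arg AC(+1,0)/(2π dx)` exact for a pure exponential; the lag-1 finite
difference is the minimal zero-lag gradient stencil a 2×2 window affords. A
brute-force O(w⁴) lag-sum implementation is kept as an independent oracle.

Masking and aggregation. Two gates select which directional estimates enter
the average:

1. **Air-floor SNR** (default threshold 2.0): per-branch window RMS against
   the air-strip RMS scaled by that filter's white-noise gain
   `sqrt(mean gain²)`. The air strip is *excluded* from the filtered region —
   a zeroed strip inside the FFT would leak energy into every branch — and
   used only as the floor estimate.
2. **Relative energy** (default 10% of the window's dominant direction):
   spectral-leakage tails of a strong wave masquerade as weak waves in other
   directions and scale with the signal, so an absolute threshold cannot
   reject them. Without this gate a single-prong 1-kHz field biases the FOV
   median by ~−17%; with it all source-count conditions sit within 5%.

Surviving directions are averaged uniformly (default) or weighted by window
energy. The map grid is the non-overlapping window tiling with one ring of
edge windows cropped (edge artifacts of the full-length FFTs): a 75×75 field
gives 37×37 windows and a 35-wide reported map. The x dimension is decimated
to the y count by Fourier resampling (band-limited, anti-aliased) before
analysis; surface slabs are averaged complex-wise starting 20 µm below the
surface. Speed and modulus: c = f0/k, G = ρc², ρ defaulting to
1000 kg/m³ (aqueous phantom).

The conventional baseline runs the identical window/gradient pipeline without
directional filtering, followed by Gaussian smoothing of the k map (σ = 2
windows, FWHM ≈ 5). Degenerate inputs: windows whose lag-1 autocorrelation
vanishes are flagged invalid (NaN), not raised; a π phase flip (standing-wave
null straddle) is at the estimator's aliasing limit and shows up as a
Nyquist-scale spike — the standing-wave analyses therefore quote medians of
the unsmoothed map, where those isolated spikes cannot move the statistic.

## RevOCE comparator

For a fully diffuse 3D shear ensemble the lateral autocorrelation of the z
displacement follows `B(x) = j0(x) − j1(x)/x` with `x = 2π k r` (the 2π
because k is in cycles/m; a convention flag exposes the plain product).
`B(0) = 2/3` analytically; the model is rescaled to 1 at zero lag to match
the normalized data profile (series expansion `2/3 − 2x²/15` below 10⁻⁶).

Per 6×6-px window: linear real autocorrelation divided by the per-lag overlap
count — the raw linear estimate carries a triangular taper that mimics faster
decay and inflates fitted k by >10% — normalized at zero lag, azimuthally
averaged by radial binning (one-pixel bins; a ray-sampling implementation is
kept as the cross-check). The fit range ends at the profile's second zero
crossing (sign-change scan with linear interpolation) when one lies within
the window, else the whole profile; a bounded least-squares solver is
initialized by matching the model's first zero (x₁ ≈ 2.77, found by
bisection) to the profile's first crossing. Non-converged or bound-pinned
fits are excluded. The window map is bilinearly upsampled to the DPGA map
grid and smoothed with σ = 2 windows.

Validity regimes (reproduced by simulation): accurate within ~10% when the
field is diffuse and the wavelength is below the 0.96-mm window extent;
biased to *high* k (low speed) when the wavelength exceeds the window; and
grossly biased (~20%) on a unidirectional field, whose azimuthal average is
J0-shaped rather than B-shaped — a smooth profile the model fits confidently
but wrongly, so the failure shows in the estimate, not the residual.

## Synthetic diffuse ensembles

`isotropic_components` spreads equal-k propagation directions over the 3D
sphere on a Fibonacci lattice with random orthogonal polarizations and random
phases. The 3D spread matters: an in-plane ring of directions has a J0
lateral autocorrelation and would disagree with the spherical-Bessel model by
construction (~15% in fitted k), which would conflate a fixture artifact with
an estimator error.

## Problem sizes and determinism

Tests and the acceptance script run the full benchtop protocol
(1394 retained × 75 × 2 A-lines per location) — plane-wave and prong
generators are closed-form, so a complete simulate→recover→map chain takes
well under a second and the whole acceptance run a few tens of seconds on one
CPU. All stochastic stages draw from `default_rng(seed)`; reports embed the
seed and a scene hash.

## Known limitations

- The recovery chain assumes the protocol's timing metadata is exact; an
  A-line-rate error leaves a predictable residual phase ramp along y (tested)
  but is not self-calibrated.
- DPGA's direction average assumes lateral isotropy of wave content per
  window; anisotropic or guided-wave media would need a different inversion.
- k estimation is 2D (en-face, depth-averaged); out-of-plane propagation
  components project onto the lateral plane and shorten the apparent
  wavenumber for strongly oblique waves.
- The edge-crop and air-strip conventions shave the usable field of view by
  one window ring plus the air rows.
- The inclusion's absolute interior wavenumber is underestimated when the
  inclusion spans only a few wavelengths (window averaging across the
  boundary); the contrast direction is robust.
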