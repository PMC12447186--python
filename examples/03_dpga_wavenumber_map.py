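"""Full chain: diffuse six-prong excitation -> recovery -> DPGA k/c/G maps.

Directional phase gradient analysis splits the field into 32 directional
branches, reads the local wavenumber from the lag-1 phase of tiny windowed
autocorrelations, masks weak directions against the air noise floor, and
averages the survivors.
"""

import numpy as np

import asyncoce as ao

f0 = 2000.0
c_true = 4.5
k_true = f0 / c_true
p = ao.benchtop_protocol(f0)

medium = ao.MediumMap(k_bg=k_true, rho_kg_m3=1000.0)
sources = ao.SourceSet(n_sources=6, amplitude_m=100e-9)
gen = ao.prong_generator(sources, medium, f0)

grid = ao.Grid.from_protocol(p)
X, Y = grid.mesh()
probe = gen(X, Y, np.zeros_like(X))
sigma = ao.sigma_for_snr(float(np.sqrt(np.mean(probe.real**2))), 20.0)

vol = ao.raster_sample(gen, p, noise_sigma=sigma, seed=7)
rec = ao.recover_volume(vol)
km = ao.analyze_volume(rec, method="dpga")

print(f"truth: k = {k_true:.1f} cycles/m (c = {c_true} m/s), SNR 20 dB, 6 prongs")
print(f"k map shape                  : {km.k.shape}")
print(f"median k                     : {km.median_k():.1f} cycles/m "
      f"({100 * (km.median_k() / k_true - 1):+.1f}% vs truth)")
print(f"median speed                 : {np.nanmedian(km.c):.2f} m/s")
print(f"median shear modulus         : {np.nanmedian(km.G) / 1e3:.1f} kPa")
print(f"windows with an estimate     : {100 * np.isfinite(km.k).mean():.0f}%")
print()
print("Each 2x2-px window spans 0.32 mm — well under the 2.25-mm wavelength —")
print("yet the phase of the complex field still resolves k inside it.")
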