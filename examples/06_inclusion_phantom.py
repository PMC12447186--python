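"""Heterogeneous phantom: a 4.5-mm soft inclusion in a stiffer background.

A softer medium carries a slower shear wave, hence a larger wavenumber at the
same excitation frequency. The full chain — six-prong excitation, raster
acquisition at 20 dB SNR, coherence recovery, DPGA — should show that
contrast even though the two regions scatter light identically.
"""

import numpy as np

import asyncoce as ao

f0 = 2000.0
c_bg, c_in = 4.5, 2.0  # m/s
p = ao.benchtop_protocol(f0)

medium = ao.MediumMap(k_bg=f0 / c_bg, k_in=f0 / c_in, inclusion_radius_m=2.25e-3)
sources = ao.SourceSet(n_sources=6, amplitude_m=100e-9)
gen = ao.prong_generator(sources, medium, f0)

grid = ao.Grid.from_protocol(p)
X, Y = grid.mesh()
sigma = ao.sigma_for_snr(float(np.sqrt(np.mean(gen(X, Y, np.zeros_like(X)).real**2))), 20.0)

vol = ao.raster_sample(gen, p, noise_sigma=sigma, seed=11)
km = ao.analyze_volume(ao.recover_volume(vol), method="dpga")

WX, WY = np.meshgrid(km.window_x - 6e-3, km.window_y - 6e-3, indexing="ij")
R = np.hypot(WX, WY)
k_in = km.median_k(R < 0.7 * 2.25e-3)
k_out = km.median_k(R > 3.25e-3)
c_map = f0 / np.array([k_in, k_out])

print(f"truth : k_in = {f0 / c_in:.0f}, k_bg = {f0 / c_bg:.0f} cycles/m")
print(f"DPGA  : median k inside  = {k_in:.0f} cycles/m  (c = {c_map[0]:.2f} m/s)")
print(f"        median k outside = {k_out:.0f} cycles/m  (c = {c_map[1]:.2f} m/s)")
print(f"        contrast (in/out) = {k_in / k_out:.2f}")
print()
print("The inclusion reads out softer (larger k, slower c) than the")
print("background. Window averaging across the 2.25-mm radius blunts the")
print("absolute value inside, but the contrast direction is unambiguous.")
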