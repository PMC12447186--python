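"""Why directional filtering matters: counter-propagating waves.

Two equal waves travelling in opposite directions form a standing field whose
complex phase is spatially constant — an undirectional phase gradient sees
k ~ 0. Splitting the field into half-plane directional branches first turns
each branch back into a clean travelling wave, and the estimate survives.
"""

import numpy as np

import asyncoce as ao

k_true = 500.0  # cycles/m
grid = ao.Grid.regular(75, 75, 12e-3)
comps = [
    ao.PlaneWaveComponent.inplane(0.0, k=k_true, s_ql=100e-9),
    ao.PlaneWaveComponent.inplane(np.pi, k=k_true, s_ql=100e-9),
]
field = ao.synthesize_true_field(comps, grid, 0.0, 2000.0)

km_conv = ao.conventional_pg(field, grid.dx, grid.dy, smooth_sigma_px=0.0)
km_dpga = ao.dpga_map(field, grid.dx, grid.dy)

print(f"true wavenumber              : {k_true:.0f} cycles/m")
print(f"conventional gradient median : {km_conv.median_k():.2f} cycles/m")
print(f"DPGA median                  : {km_dpga.median_k():.1f} cycles/m")
print()
print("The conventional estimate collapses to ~0 (constant phase between the")
print("interference nulls), while the directional branches each see a single")
print("travelling wave and recover k essentially exactly.")
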