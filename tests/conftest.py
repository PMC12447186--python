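"""Shared fixtures: protocols, scenes, and simulated fields.

Everything is generated programmatically at test time; seeds are fixed so the
suite is deterministic.
"""

import numpy as np
import pytest

import asyncoce as ao

# phantom-like shear speeds per excitation frequency (m/s)
SPEEDS = {1000.0: 3.5, 2000.0: 4.5}


@pytest.fixture(scope="session")
def protocol_1k():
    return ao.benchtop_protocol(1000.0)


@pytest.fixture(scope="session")
def protocol_2k():
    return ao.benchtop_protocol(2000.0)


@pytest.fixture(scope="session")
def grid75():
    """75 x 75 lateral grid over the 12 x 12 mm field of view."""
    return ao.Grid.regular(75, 75, 12e-3)


def make_prong_volume(f0_hz, n_sources, *, amp_scale=1.0, snr_db=20.0, seed=7, swap_axes=False):
    """Full-protocol raster acquisition of a prong-excited homogeneous phantom."""
    prot = ao.benchtop_protocol(f0_hz)
    k_true = f0_hz / SPEEDS[f0_hz]
    medium = ao.MediumMap(k_bg=k_true)
    sources = ao.SourceSet(n_sources=n_sources, amplitude_m=100e-9 * amp_scale)
    gen = ao.prong_generator(sources, medium, f0_hz)
    sigma = 0.0
    if snr_db is not None:
        grid = ao.Grid.from_protocol(prot)
        X, Y = grid.mesh()
        probe = gen(X, Y, np.zeros_like(X))
        sigma = ao.sigma_for_snr(float(np.sqrt(np.mean(probe.real**2))), snr_db)
    vol = ao.raster_sample(gen, prot, noise_sigma=sigma, seed=seed, swap_axes=swap_axes)
    return vol, k_true


@pytest.fixture(scope="session")
def diffuse_volume_2k():
    """Six-prong, 2-kHz acquisition at 20 dB displacement SNR."""
    return make_prong_volume(2000.0, 6)
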