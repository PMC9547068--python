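"""Shared fixtures: small-scale simulated acquisitions reused across tests.

The expensive wave-optics stacks are session-scoped; every test derives what
it needs (sub-stacks, estimators, refocused planes) from them.
"""

from __future__ import annotations

import numpy as np
import pytest

from clm import OpticalConfig, estimate_gamma
from clm.correlation import FrameStack
from clm.optics import simulate_arrays
from clm.phantoms import ThickSample, TransmissionMask, triple_slit


@pytest.fixture(scope="session")
def config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def focused_slit_stack(config) -> FrameStack:
    """8000 paired frames of a focused triple slit (d = 30 µm) on a small
    grid: 128^2 simulation, 32^2 arm a, 8^2 arm b."""
    dx = config.band_limit_spacing
    n = 128
    mask = triple_slit(30e-6, fov=n * dx, spacing=dx)
    sample = ThickSample(planes=((0.0, mask),))
    ia, ib, ca, cb = simulate_arrays(
        sample, config, 8000, seed=101, sim_size=n, bin_a=4, bin_b=16
    )
    return FrameStack(frames_a=ia, frames_b=ib, coords_a=ca, coords_b=cb)


@pytest.fixture(scope="session")
def focused_slit_gamma(focused_slit_stack):
    return estimate_gamma(focused_slit_stack)


@pytest.fixture(scope="session")
def illumination_stack(config) -> FrameStack:
    """2500 empty-sample frames (pure chaotic illumination) on a 64^2 grid,
    unbinned arm a, for the photon-statistics checks."""
    ia, ib, ca, cb = simulate_arrays(
        None, config, 2500, seed=202, sim_size=64, bin_a=1, bin_b=8
    )
    return FrameStack(frames_a=ia, frames_b=ib, coords_a=ca, coords_b=cb)


def pinhole_mask(n: int, dx: float, x0: float = 0.0, y0: float = 0.0, r0: float = 8e-6):
    """Open circular aperture (bright point-like transmitter) on opaque field."""
    c = (np.arange(n) - n // 2) * dx
    xx, yy = np.meshgrid(c, c)
    v = np.zeros((n, n))
    v[(xx - x0) ** 2 + (yy - y0) ** 2 <= r0**2] = 1.0
    return TransmissionMask(v, dx, n * dx)


def granule_mask(n: int, dx: float, x0: float = 0.0, y0: float = 0.0, r0: float = 20e-6):
    """Opaque disk (dark granule) on a transparent field."""
    c = (np.arange(n) - n // 2) * dx
    xx, yy = np.meshgrid(c, c)
    v = np.ones((n, n))
    v[(xx - x0) ** 2 + (yy - y0) ** 2 <= r0**2] = 0.0
    return TransmissionMask(v, dx, n * dx)
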