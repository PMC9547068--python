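"""Centered-grid helpers shared by the optics engine and the estimators.

All physical coordinates are in meters.  A grid of ``n`` samples with spacing
``dx`` carries centered coordinates ``(i - n//2) * dx`` so the optical axis
falls on the center of pixel ``n//2``.  Image inversion (the minus sign in the
conjugate-point mapping) is applied as a *periodic* index flip, which maps
pixel centers exactly onto pixel centers on an FFT grid.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "centered_coords",
    "freq_coords",
    "periodic_flip",
    "block_bin",
    "block_bin_coords",
]


def centered_coords(n: int, dx: float) -> np.ndarray:
    """Physical coordinates of pixel centers, axis on pixel ``n//2``."""
    return (np.arange(n) - n // 2) * float(dx)


def freq_coords(n: int, dx: float) -> np.ndarray:
    """Centered spatial-frequency coordinates matching ``fftshift`` layout."""
    return np.fft.fftshift(np.fft.fftfreq(n, d=dx))


def periodic_flip(a: np.ndarray) -> np.ndarray:
    """Spatial inversion x -> -x on a periodic centered grid.

    ``out[i] = a[(-i) mod n]`` along both trailing axes; exact (no
    interpolation) and an involution.
    """
    out = a
    for ax in (-2, -1):
        out = np.roll(np.flip(out, axis=ax), 1, axis=ax)
    return out


def block_bin(a: np.ndarray, factor: int) -> np.ndarray:
    """Block-sum binning of the two trailing axes by an integer factor."""
    if factor == 1:
        return a
    *lead, h, w = a.shape
    if h % factor or w % factor:
        raise ValueError(f"shape {(h, w)} not divisible by binning {factor}")
    return a.reshape(*lead, h // factor, factor, w // factor, factor).sum(axis=(-3, -1))


def block_bin_coords(coords: np.ndarray, factor: int) -> np.ndarray:
    """Coordinates of block centers after binning by ``factor``."""
    if factor == 1:
        return coords
    n = coords.size
    if n % factor:
        raise ValueError(f"length {n} not divisible by binning {factor}")
    return coords.reshape(n // factor, factor).mean(axis=1)
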