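"""Shift-and-sum reconstruction from the 4D correlation tensor.

Each arm-b cell rho_b is a viewpoint on the objective lens (the lens point
rho_O = -rho_b / M_L).  Refocusing at an axial distance f from the objective
re-registers every viewpoint's image by the defocus-dependent affine remap

    Sigma_ref(rho_a) = sum_b Gamma( (f_O/f) rho_a + (1 - f_O/f) (M/M_L) rho_b,  rho_b )

sampled by bilinear interpolation on the arm-a grid; samples falling off the
detector are dropped and the sum is divided per pixel by the number of
contributing viewpoints (edge-overlap normalization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .config import OpticalConfig
from .correlation import CorrelationTensor

__all__ = ["RefocusedImage", "PerspectiveImage", "refocus", "viewpoint", "refocus_stack", "depth_map"]


@dataclass(frozen=True)
class RefocusedImage:
    """Refocused plane: map over the arm-a detector coordinate rho_a."""

    values: np.ndarray
    coords_a: np.ndarray
    f: float  # refocus distance from the objective (m)
    z: float  # f - f_O (m)
    overlap: np.ndarray  # contributing-viewpoint count per pixel
    estimator: str = "plain"

    def __post_init__(self) -> None:
        if self.values.shape != self.overlap.shape:
            raise ValueError("overlap map must match the image shape")
        if np.any(self.overlap < 0):
            raise ValueError("overlap counts must be >= 0")

    def upright(self, magnification: float) -> tuple[np.ndarray, np.ndarray]:
        """Image re-inverted to upright object-side coordinates.

        Returns ``(values, coords)`` with ``coords`` in meters at the sample:
        the detector pixel at rho_a maps to the object point -rho_a / M.
        """
        vals = self.values[::-1, ::-1]
        coords = -self.coords_a[::-1] / magnification
        return vals, coords


@dataclass(frozen=True)
class PerspectiveImage:
    """Single-viewpoint image: Gamma averaged over a small arm-b patch."""

    values: np.ndarray
    coords_a: np.ndarray
    center_b: tuple[float, float]  # (x_b, y_b) viewpoint center on D_b (m)
    lens_point: tuple[float, float] | None  # rho_O = -rho_b / M_L (m)
    patch: int


def _interp_grid(plane: np.ndarray, coords: np.ndarray, sx: np.ndarray, sy: np.ndarray):
    """Bilinear sample of ``plane`` (indexed [y, x] on ``coords``) at physical
    positions (sy, sx); returns (samples, validity mask)."""
    d = coords[1] - coords[0]
    iy = (sy - coords[0]) / d
    ix = (sx - coords[0]) / d
    valid = (iy >= 0) & (iy <= len(coords) - 1) & (ix >= 0) & (ix <= len(coords) - 1)
    out = ndimage.map_coordinates(plane, [iy, ix], order=1, mode="constant", cval=0.0)
    return out, valid


def refocus(gamma: CorrelationTensor, f: float, config: OpticalConfig) -> RefocusedImage:
    """Refocus the correlation tensor on the plane at distance ``f`` from the
    objective (f = f_O reproduces the summed correlation image exactly)."""
    if f <= 0:
        raise ValueError("refocus distance f must be > 0")
    f_o = config.objective_focal
    scale = f_o / f
    shift_gain = (1.0 - scale) * config.magnification / config.lens_arm_magnification

    ca = np.asarray(gamma.coords_a, dtype=float)
    cb = np.asarray(gamma.coords_b, dtype=float)
    ya, xa = np.meshgrid(ca, ca, indexing="ij")
    acc = np.zeros((len(ca), len(ca)))
    count = np.zeros_like(acc)
    for jy, vb in enumerate(cb):
        for jx, ub in enumerate(cb):
            sy = scale * ya + shift_gain * vb
            sx = scale * xa + shift_gain * ub
            vals, valid = _interp_grid(gamma.values[:, :, jy, jx], ca, sx, sy)
            acc += np.where(valid, vals, 0.0)
            count += valid
    if not np.any(count):
        raise ValueError("refocus remap falls entirely outside the arm-a detector")
    out = np.divide(acc, count, out=np.zeros_like(acc), where=count > 0)
    return RefocusedImage(
        values=out, coords_a=ca, f=f, z=f - f_o, overlap=count, estimator=gamma.estimator
    )


def viewpoint(
    gamma: CorrelationTensor,
    center_b: tuple[float, float],
    patch: int = 10,
    config: OpticalConfig | None = None,
) -> PerspectiveImage:
    """Perspective view from the arm-b patch centered on ``center_b`` (m)."""
    cb = np.asarray(gamma.coords_b, dtype=float)
    nb = len(cb)
    jx = int(np.argmin(np.abs(cb - center_b[0])))
    jy = int(np.argmin(np.abs(cb - center_b[1])))
    half_lo = (patch - 1) // 2
    ylo, xlo = jy - half_lo, jx - half_lo
    if patch < 1 or ylo < 0 or xlo < 0 or ylo + patch > nb or xlo + patch > nb:
        raise ValueError(
            f"{patch}x{patch} patch at cell ({jy}, {jx}) exceeds the {nb}x{nb} arm-b ROI"
        )
    block = gamma.values[:, :, ylo : ylo + patch, xlo : xlo + patch]
    center = (float(cb[xlo : xlo + patch].mean()), float(cb[ylo : ylo + patch].mean()))
    lens_point = None
    if config is not None:
        ml = config.lens_arm_magnification
        lens_point = (-center[0] / ml, -center[1] / ml)
    return PerspectiveImage(
        values=block.mean(axis=(2, 3)),
        coords_a=np.asarray(gamma.coords_a, dtype=float),
        center_b=center,
        lens_point=lens_point,
        patch=patch,
    )


def refocus_stack(
    gamma: CorrelationTensor, z_list: Sequence[float], config: OpticalConfig
) -> list[RefocusedImage]:
    """Refocus at each offset z = f - f_O in ``z_list`` (order preserved)."""
    return [refocus(gamma, config.objective_focal + z, config) for z in z_list]


def depth_map(
    stack: Sequence[RefocusedImage],
    window: int = 9,
    smooth: float = 2.0,
    energy_threshold: float = 0.1,
    metric_threshold: float = 1e-9,
) -> np.ndarray:
    """Per-window depth estimate from a refocused stack.

    The focus metric is the local normalized variance (local variance over
    squared local mean) in a ``window``-pixel neighborhood, computed after a
    Gaussian pre-smoothing of ``smooth`` pixels that suppresses the
    pixel-scale statistical noise of the correlation estimate (which would
    otherwise dominate the variance); each pixel gets the z of the plane
    maximizing the metric.  Windows whose local energy falls below
    ``energy_threshold`` times the global mean energy, or whose best metric
    is below ``metric_threshold``, are undefined (NaN).
    """
    if len(stack) < 3:
        raise ValueError("need at least 3 refocused planes for a depth map")
    zs = np.array([im.z for im in stack])
    metrics = []
    energies = []
    for im in stack:
        v = ndimage.gaussian_filter(im.values, smooth) if smooth > 0 else im.values
        mu = ndimage.uniform_filter(v, window)
        var = ndimage.uniform_filter(v * v, window) - mu * mu
        metrics.append(var / np.maximum(mu * mu, np.finfo(float).tiny))
        energies.append(mu)
    metrics = np.stack(metrics)
    energies = np.stack(energies)
    best = np.argmax(metrics, axis=0)
    zmap = zs[best]
    peak_metric = np.take_along_axis(metrics, best[None], axis=0)[0]
    peak_energy = energies.max(axis=0)
    undefined = (peak_energy < energy_threshold * float(energies.mean())) | (
        peak_metric < metric_threshold
    )
    zmap = np.where(undefined, np.nan, zmap)
    return zmap
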