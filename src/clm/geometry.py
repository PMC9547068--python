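"""Closed-form geometrical-optics model of the correlation function.

In the geometrical limit the 4D correlation of a thin plane at distance f
from the objective factorizes into the sample intensity profile F and the
pupil transmission P:

    Gamma(rho_a, rho_b) ~ F^2( -(f/f_T) rho_a - (1 - f/f_O) rho_b/M_L ) * P^2( -rho_b/M_L )

This deterministic forward model is the oracle for the wave simulator (shape
agreement for features well above the diffraction limit) and for the refocus
kernel (whose remap inverts the F argument exactly).  Absolute scale is not
defined; all comparisons are shape-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import OpticalConfig
from .correlation import CorrelationTensor
from .phantoms import ThickSample, TransmissionMask

__all__ = ["PupilSpec", "gamma_geometric", "circle_of_confusion"]


@dataclass(frozen=True)
class PupilSpec:
    """Objective intensity transmission: circular iris of radius R (m), or an
    arbitrary grayscale map in [0, 1] on a centered grid."""

    radius: float
    grayscale: np.ndarray | None = None
    grayscale_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pupil radius must be > 0")
        if self.grayscale is not None:
            g = np.asarray(self.grayscale, dtype=float)
            if g.min() < 0 or g.max() > 1:
                raise ValueError("pupil transmission must lie in [0, 1]")
            if self.grayscale_spacing is None or self.grayscale_spacing <= 0:
                raise ValueError("grayscale pupil needs a positive grid spacing")
            object.__setattr__(self, "grayscale", g)

    def transmission(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """P(rho_O) at lens-plane positions (m)."""
        if self.grayscale is None:
            return (x**2 + y**2 <= self.radius**2).astype(float)
        n = self.grayscale.shape[0]
        d = self.grayscale_spacing
        iy = y / d + n // 2
        ix = x / d + n // 2
        return ndimage.map_coordinates(self.grayscale, [iy, ix], order=1, cval=0.0)


def _sample_f2(f2: np.ndarray, c0: float, d: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear sample of a precomputed F^2 map at object positions (m);
    zero outside the mask extent."""
    iy = (y - c0) / d
    ix = (x - c0) / d
    return ndimage.map_coordinates(f2, [iy, ix], order=1, mode="constant", cval=0.0)


def gamma_geometric(
    sample: ThickSample,
    config: OpticalConfig,
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    pupil: PupilSpec | None = None,
) -> CorrelationTensor:
    """Evaluate the geometric correlation on the requested detector grids.

    Multi-plane samples are composed additively (incoherent sum of per-plane
    correlations); occlusion between planes is deliberately not modeled here —
    it exists only in the wave simulator's multi-slice chain.
    """
    if pupil is None:
        pupil = PupilSpec(radius=config.pupil_radius)
    ca = np.asarray(coords_a, dtype=float)
    cb = np.asarray(coords_b, dtype=float)
    ml = config.lens_arm_magnification
    f_t = config.tube_focal
    f_o = config.objective_focal

    lens_x = -cb[None, :] / ml  # rho_O grid seen through arm b
    lens_y = -cb[:, None] / ml
    p2 = pupil.transmission(np.broadcast_to(lens_x, (len(cb), len(cb))),
                            np.broadcast_to(lens_y, (len(cb), len(cb)))) ** 2

    ya, xa = np.meshgrid(ca, ca, indexing="ij")
    values = np.zeros((len(ca), len(ca), len(cb), len(cb)))
    for z, mask in sample.planes:
        f = f_o + z
        gain = -(1.0 - f / f_o) / ml  # coefficient of rho_b in the F argument
        f2 = mask.values**2
        c0, d = mask.coords()[0], mask.spacing
        for jy, vb in enumerate(cb):
            for jx, ub in enumerate(cb):
                sx = -(f / f_t) * xa + gain * ub
                sy = -(f / f_t) * ya + gain * vb
                values[:, :, jy, jx] += _sample_f2(f2, c0, d, sx, sy)
    values *= p2[None, None, :, :]
    return CorrelationTensor(
        values=values, coords_a=ca, coords_b=cb, estimator="oracle:geometric", n_frames=0
    )


def circle_of_confusion(
    z: float,
    f: float,
    a: float,
    config: OpticalConfig,
    pupil: PupilSpec | None = None,
) -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    """Defocused-refocus geometry for two point sources separated by ``a``.

    Two points on a plane at distance ``z`` from the objective, refocused at
    distance ``f``, each spread into a circle of confusion of radius
    M R |f - z| / z, centered at +/- (M f / (2 z)) a on the x axis.  At
    ``f = z`` the radius is exactly zero (points refocused at truth).
    """
    if z <= 0 or f <= 0:
        raise ValueError("z and f must be > 0")
    r_pupil = config.pupil_radius if pupil is None else pupil.radius
    m = config.magnification
    radius = m * r_pupil * abs(f - z) / z
    cx = m * f * a / (2.0 * z)
    return radius, ((cx, 0.0), (-cx, 0.0))
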