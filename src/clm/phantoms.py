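"""Synthetic test objects: slit resolution targets and granule suspensions.

Samples are stacks of thin transmission planes at axial offsets ``z = f - f_O``
from the objective focal plane (``z > 0``: farther from the objective).  Masks
store *amplitude* transmission in [0, 1]; all targets here are binary, for
which amplitude and intensity transmission coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._grids import centered_coords

__all__ = [
    "TransmissionMask",
    "ThickSample",
    "triple_slit",
    "two_plane_target",
    "granule_phantom",
]

#: overall linear field of view of the reference instrument (m)
DEFAULT_FOV = 0.54e-3


@dataclass(frozen=True)
class TransmissionMask:
    """2D transmission map in [0, 1] on a centered square grid."""

    values: np.ndarray
    spacing: float
    fov: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("mask must be 2D")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("transmission values must lie in [0, 1]")
        if self.spacing <= 0 or self.fov <= 0:
            raise ValueError("spacing and fov must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def coords(self) -> np.ndarray:
        """Pixel-center coordinates along either axis (m)."""
        return centered_coords(self.values.shape[-1], self.spacing)


@dataclass(frozen=True)
class ThickSample:
    """Ordered set of transmission planes at strictly increasing offsets."""

    planes: tuple[tuple[float, TransmissionMask], ...]
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        planes = tuple(self.planes)
        offsets = [z for z, _ in planes]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError(f"axial offsets must be strictly increasing, got {offsets}")
        object.__setattr__(self, "planes", planes)

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([z for z, _ in self.planes])


def _grid_size(fov: float, spacing: float) -> int:
    n = int(round(fov / spacing))
    if n < 2:
        raise ValueError("fov/spacing yields an empty grid")
    return n


def triple_slit(
    d: float,
    slit_width: float | None = None,
    orientation: str = "x",
    fov: float = DEFAULT_FOV,
    spacing: float = 1.0e-6,
    center: float = 0.0,
    window: float | None = None,
) -> TransmissionMask:
    """Binary triple-slit mask: opaque backing with three open slits.

    Parameters
    ----------
    d : center-to-center slit distance (m).
    slit_width : open width of each slit (m); defaults to ``d / 2``.
    orientation : ``"x"`` — profile varies along x (slits run along y) — or
        ``"y"`` for the transpose.
    center : lateral offset of the central slit along the profile axis (m).
    window : width of the opaque backing region around ``center`` along the
        profile axis (m); outside it the slide is transparent.  ``None``
        (default) makes the backing span the whole field of view, as for a
        single resolution target filling the field.
    """
    a = d / 2 if slit_width is None else slit_width
    if a <= 0 or d <= 0:
        raise ValueError("d and slit_width must be > 0")
    if a > d:
        raise ValueError(f"slit_width {a} exceeds center-to-center distance {d}")
    if orientation not in ("x", "y"):
        raise ValueError("orientation must be 'x' or 'y'")
    if abs(center) + d + a / 2 > fov / 2:
        raise ValueError(
            f"triple slit (span {2 * d + a:.3g} m at center {center:.3g} m) "
            f"does not fit in fov {fov:.3g} m"
        )
    if window is not None and window < 2 * d + a:
        raise ValueError(f"backing window {window:.3g} m narrower than the slit span")
    n = _grid_size(fov, spacing)
    x = centered_coords(n, spacing)
    profile = np.zeros(n)
    if window is not None:
        # half-open backing so two abutting slides never overlap
        profile[np.abs(x - center) >= window / 2] = 1.0
    for k in (-1, 0, 1):
        profile[np.abs(x - (center + k * d)) <= a / 2] = 1.0
    values = np.tile(profile, (n, 1))
    if orientation == "y":
        values = values.T
    return TransmissionMask(values=values, spacing=spacing, fov=fov)


def two_plane_target(
    d: float = 49.6e-6,
    offsets: tuple[float, float] = (-1250e-6, 1250e-6),
    fov: float = DEFAULT_FOV,
    spacing: float = 1.0e-6,
    slit_width: float | None = None,
) -> ThickSample:
    """Two laterally disjoint triple-slit planes straddling the focal plane.

    Defaults reproduce the two-target volumetric experiment: center-to-center
    distance 49.6 µm, planes at -1250 µm and +1250 µm (2.5 mm apart), each
    triple-slit group in the opposite half of the field of view so both are
    visible at once.  Each target's opaque backing covers only its own half of
    the field (separate physical slides, clear outside the pattern region), so
    the far plane is spatially filtered by the near one but not extinguished.
    """
    z1, z2 = offsets
    if z1 == z2:
        raise ValueError("the two plane offsets must be distinct")
    lo, hi = sorted(offsets)
    m_lo = triple_slit(d, slit_width, fov=fov, spacing=spacing, center=-fov / 4, window=fov / 2)
    m_hi = triple_slit(d, slit_width, fov=fov, spacing=spacing, center=+fov / 4, window=fov / 2)
    return ThickSample(
        planes=((lo, m_lo), (hi, m_hi)),
        name="two_plane_target",
        meta={"d": d, "offsets": [lo, hi], "centers": [-fov / 4, fov / 4]},
    )


def granule_phantom(
    n: int,
    volume: tuple[float, float, float] = (1e-3, 1e-3, 1e-3),
    radius_range: tuple[float, float] = (10e-6, 40e-6),
    n_slices: int = 8,
    seed: int = 0,
    spacing: float = 2.0e-6,
) -> ThickSample:
    """Randomly placed opaque-disk granules in a transparent volume.

    ``n`` granules get seeded uniform positions inside ``volume`` (centered on
    the optical axis and the focal plane) and uniform radii in
    ``radius_range``; each granule is stamped onto the nearest of ``n_slices``
    transmission planes spanning the z extent, so the axial quantization error
    is at most half the slice spacing.
    """
    if n < 1:
        raise ValueError("need at least one granule")
    lx, ly, lz = volume
    if min(lx, ly, lz) <= 0:
        raise ValueError("volume extents must be > 0")
    if n_slices < 1:
        raise ValueError("need at least one slice")
    r_lo, r_hi = radius_range
    fov = max(lx, ly)
    if 2 * r_hi > fov:
        raise ValueError(f"granule diameter {2 * r_hi:.3g} m exceeds fov {fov:.3g} m")

    rng = np.random.default_rng(seed)
    xy = rng.uniform([-lx / 2, -ly / 2], [lx / 2, ly / 2], size=(n, 2))
    zs = rng.uniform(-lz / 2, lz / 2, size=n)
    radii = rng.uniform(r_lo, r_hi, size=n)

    dz = lz / n_slices
    plane_z = (np.arange(n_slices) + 0.5) * dz - lz / 2
    which = np.argmin(np.abs(zs[:, None] - plane_z[None, :]), axis=1)

    ngrid = _grid_size(fov, spacing)
    c = centered_coords(ngrid, spacing)
    xx, yy = np.meshgrid(c, c)
    planes = []
    for j in range(n_slices):
        idx = np.flatnonzero(which == j)
        if idx.size == 0:
            continue
        vals = np.ones((ngrid, ngrid))
        for i in idx:
            vals[(xx - xy[i, 0]) ** 2 + (yy - xy[i, 1]) ** 2 <= radii[i] ** 2] = 0.0
        planes.append((plane_z[j], TransmissionMask(vals, spacing, fov)))
    meta = {
        "positions": np.column_stack([xy, zs]).tolist(),
        "radii": radii.tolist(),
        "slice_z": plane_z.tolist(),
        "assigned_slice": which.tolist(),
        "volume": list(volume),
        "seed": int(seed),
    }
    return ThickSample(planes=tuple(planes), name="granule_phantom", meta=meta)


def sample_to_json(sample: ThickSample) -> str:
    """Serialize a phantom description (not the pixel data) to JSON."""
    return json.dumps(
        {
            "name": sample.name,
            "offsets": sample.offsets.tolist(),
            "meta": sample.meta,
        },
        indent=2,
    )


def granule_phantom_from_json(doc: str, spacing: float = 2.0e-6) -> ThickSample:
    """Rebuild a granule phantom from its JSON description (positions, radii,
    slice planes) — the exact discretization, not a re-draw."""
    data = json.loads(doc)
    meta = data["meta"]
    pos = np.asarray(meta["positions"])
    radii = np.asarray(meta["radii"])
    plane_z = np.asarray(meta["slice_z"])
    which = np.asarray(meta["assigned_slice"])
    lx, ly, _ = meta["volume"]
    fov = max(lx, ly)
    n = _grid_size(fov, spacing)
    c = centered_coords(n, spacing)
    xx, yy = np.meshgrid(c, c)
    planes = []
    for j in range(len(plane_z)):
        idx = np.flatnonzero(which == j)
        if idx.size == 0:
            continue
        vals = np.ones((n, n))
        for i in idx:
            vals[(xx - pos[i, 0]) ** 2 + (yy - pos[i, 1]) ** 2 <= radii[i] ** 2] = 0.0
        planes.append((plane_z[j], TransmissionMask(vals, spacing, fov)))
    return ThickSample(planes=tuple(planes), name=data.get("name", ""), meta=meta)
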