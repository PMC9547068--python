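"""Scalar wave-optics engine for chaotic-light (pseudo-thermal) microscopy.

One simulated frame is one coherence time of the source: an independent
circular-Gaussian speckle field is drawn, propagated through the thick sample
(multi-slice: transmit, free-propagate), clipped by the objective pupil, and
split losslessly into the two detection arms —

* arm a (spatial): ideal 4f image of the objective focal plane,
  magnification ``-M`` with ``M = f_T/f_O``;
* arm b (angular): image of the objective pupil, magnification ``-M_L``.

Free-space propagation is exact scalar (angular-spectrum) diffraction on the
grid; the imaging arms use the equivalent Fourier-plane formulation (pupil
applied to the spectrum of the focal-plane field), so both arms share one
post-pupil field as in the physical beam-splitter layout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable

import numpy as np
from scipy import fft as sp_fft

from ._grids import block_bin, block_bin_coords, centered_coords, freq_coords, periodic_flip
from .config import DetectorSpec, OpticalConfig
from .phantoms import ThickSample

__all__ = [
    "ComplexField",
    "FramePair",
    "sample_source_field",
    "propagate",
    "apply_lens",
    "simulate_frame_pair",
    "simulate_arrays",
    "detector_coords",
    "max_safe_distance",
]


@dataclass(frozen=True)
class ComplexField:
    """Monochromatic complex amplitude on a centered square grid."""

    amplitude: np.ndarray
    spacing: float
    wavelength: float
    z: float = 0.0  # axial plane label (m), offset from the focal plane

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitude)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("field must be a square 2D array")
        if not np.iscomplexobj(a):
            a = a.astype(np.complex128)
        object.__setattr__(self, "amplitude", a)
        if self.spacing <= 0 or self.wavelength <= 0:
            raise ValueError("spacing and wavelength must be > 0")

    @property
    def n(self) -> int:
        return self.amplitude.shape[0]

    def power(self) -> float:
        """Total power sum(|E|^2) * dx^2."""
        return float(np.sum(np.abs(self.amplitude) ** 2)) * self.spacing**2

    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2


@dataclass(frozen=True)
class FramePair:
    """One coherence-time exposure on both arms, from a single source field."""

    intensity_a: np.ndarray
    intensity_b: np.ndarray
    seed: int
    index: int = 0

    def __post_init__(self) -> None:
        if np.any(self.intensity_a < 0) or np.any(self.intensity_b < 0):
            raise ValueError("intensities must be non-negative")


def _check_band_limit(spacing: float, config: OpticalConfig) -> None:
    limit = config.band_limit_spacing
    if spacing > limit * (1 + 1e-9):
        raise ValueError(
            f"grid spacing {spacing:.3e} m too coarse for NA0 = "
            f"{config.numerical_aperture}: need spacing <= lambda/(2 NA0) = {limit:.3e} m"
        )


def sample_source_field(
    config: OpticalConfig,
    n: int,
    spacing: float,
    seed: int,
    enforce_band_limit: bool = True,
) -> ComplexField:
    """Draw one chaotic-source realization: i.i.d. circular complex Gaussian
    amplitude confined to the source spot (delta-correlated diffuser model).

    If the spot diameter exceeds the grid extent the field fills the grid
    (the spot is effectively infinite at this scale).
    """
    if enforce_band_limit:
        _check_band_limit(spacing, config)
    rng = np.random.default_rng(seed)
    amp = (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))) / np.sqrt(2)
    radius = config.source_spot_diameter / 2
    if radius < n * spacing / 2:
        c = centered_coords(n, spacing)
        xx, yy = np.meshgrid(c, c)
        amp = amp * (xx**2 + yy**2 <= radius**2)
    return ComplexField(amp, spacing, config.wavelength, z=config.source_to_sample_distance)


def max_safe_distance(n: int, spacing: float, wavelength: float) -> float:
    """Largest |z| for which the grid's steepest plane wave does not wrap
    around the periodic window: z_max = n * dx^2 / lambda."""
    return n * spacing**2 / wavelength


def propagate(field: ComplexField, distance: float, strict: bool = False) -> ComplexField:
    """Free-space angular-spectrum propagation by ``distance`` (m, signed).

    Exact scalar diffraction with periodic boundaries; unitary (power
    conserving) because the grids used here carry no evanescent components.
    With ``strict=True`` the wraparound (aliasing) criterion is enforced and
    a violating distance raises, naming the maximum safe distance.
    """
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    if distance == 0.0:
        return field
    if strict:
        zmax = max_safe_distance(field.n, field.spacing, field.wavelength)
        if abs(distance) > zmax:
            raise ValueError(
                f"propagation over {distance:.3e} m aliases on this grid; "
                f"maximum safe distance is {zmax:.3e} m"
            )
    single = field.amplitude.dtype == np.complex64
    h = _transfer_function(field.n, field.spacing, field.wavelength, float(distance), single)
    out = sp_fft.ifft2(sp_fft.fft2(field.amplitude) * h)
    return replace(field, amplitude=out, z=field.z - distance)


@lru_cache(maxsize=32)
def _transfer_function(
    n: int, spacing: float, wavelength: float, distance: float, single: bool
) -> np.ndarray:
    """Angular-spectrum transfer function (evanescent components dropped)."""
    nu = np.fft.fftfreq(n, d=spacing)
    kz2 = 1.0 / wavelength**2 - (nu[:, None] ** 2 + nu[None, :] ** 2)
    prop = kz2 > 0
    h = np.exp(2j * np.pi * distance * np.sqrt(np.where(prop, kz2, 0.0))) * prop
    h.setflags(write=False)
    return h.astype(np.complex64) if single else h


def apply_lens(field: ComplexField, focal_length: float) -> ComplexField:
    """Thin-lens quadratic phase exp(-i pi rho^2 / (lambda f)); pure phase."""
    if focal_length == 0:
        raise ValueError("focal_length must be nonzero")
    c = centered_coords(field.n, field.spacing)
    rho2 = c[:, None] ** 2 + c[None, :] ** 2
    phase = np.exp(-1j * np.pi * rho2 / (field.wavelength * focal_length))
    return replace(field, amplitude=field.amplitude * phase)


# ---------------------------------------------------------------------------
# frame-pair formation


def _cfft2(a: np.ndarray) -> np.ndarray:
    return sp_fft.fftshift(sp_fft.fft2(sp_fft.ifftshift(a), norm="ortho"))


def _cifft2(a: np.ndarray) -> np.ndarray:
    return sp_fft.fftshift(sp_fft.ifft2(sp_fft.ifftshift(a), norm="ortho"))


def _pupil_mask(n: int, spacing: float, config: OpticalConfig) -> np.ndarray:
    return _pupil_mask_cached(
        n, spacing, config.wavelength, config.objective_focal, config.pupil_radius
    )


@lru_cache(maxsize=32)
def _pupil_mask_cached(
    n: int, spacing: float, wavelength: float, f_o: float, radius: float
) -> np.ndarray:
    """Objective iris of radius R evaluated on the Fourier-plane grid
    rho_O = lambda * f_O * nu."""
    rho = wavelength * f_o * freq_coords(n, spacing)
    rr2 = rho[:, None] ** 2 + rho[None, :] ** 2
    mask = rr2 <= radius**2
    mask.setflags(write=False)
    return mask


def detector_coords(
    config: OpticalConfig,
    n: int,
    spacing: float,
    bin_a: int,
    bin_b: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Physical pixel-center coordinates (m) on detectors D_a and D_b for a
    simulation grid of ``n`` samples at sample-plane ``spacing``."""
    coords_a = block_bin_coords(config.magnification * centered_coords(n, spacing), bin_a)
    drho = config.wavelength * config.objective_focal / (n * spacing)
    coords_b = block_bin_coords(
        config.lens_arm_magnification * centered_coords(n, drho), bin_b
    )
    return coords_a, coords_b


def _resolve_binning(n: int, detectors: tuple[DetectorSpec, DetectorSpec] | None,
                     bin_a: int, bin_b: int) -> tuple[int, int]:
    if detectors is not None:
        da, db = detectors
        for name, spec in (("a", da), ("b", db)):
            if spec.shape[0] != spec.shape[1] or n % spec.shape[0]:
                raise ValueError(
                    f"arm-{name} detector shape {spec.shape} must be square and "
                    f"divide the simulation grid ({n})"
                )
        return n // da.shape[0], n // db.shape[0]
    return bin_a, bin_b


def simulate_frame_pair(
    sample: ThickSample | None,
    config: OpticalConfig,
    detectors: tuple[DetectorSpec, DetectorSpec] | None = None,
    seed: int = 0,
    *,
    frame_index: int = 0,
    sim_size: int = 512,
    spacing: float | None = None,
    bin_a: int = 4,
    bin_b: int = 16,
    illumination: str = "auto",
    dtype: type = np.complex64,
) -> FramePair:
    """Simulate one paired exposure of both arms from one source realization.

    The illumination path is chosen from the source geometry: if the source
    coherence width at the sample, lambda*z/D, is below the grid spacing (the
    reference geometry: 8 mm spot, 10 mm away), the field is drawn as
    delta-correlated speckle directly at the first sample plane; otherwise it
    is drawn at the source plane and propagated.  ``illumination`` may force
    ``"direct"`` or ``"propagated"``.
    """
    prep = _prepare_simulation(
        sample, config, detectors, sim_size=sim_size, spacing=spacing,
        bin_a=bin_a, bin_b=bin_b, illumination=illumination, dtype=dtype,
    )
    i_a, i_b = _simulate_one(prep, seed, frame_index)
    return FramePair(intensity_a=i_a, intensity_b=i_b, seed=seed, index=frame_index)


def _prepare_simulation(
    sample: ThickSample | None,
    config: OpticalConfig,
    detectors: tuple[DetectorSpec, DetectorSpec] | None,
    *,
    sim_size: int,
    spacing: float | None,
    bin_a: int,
    bin_b: int,
    illumination: str,
    dtype: type,
) -> dict:
    """Validate grids once and precompute everything reused across frames."""
    dx = config.band_limit_spacing if spacing is None else spacing
    _check_band_limit(dx, config)
    bin_a, bin_b = _resolve_binning(sim_size, detectors, bin_a, bin_b)
    if sim_size % bin_a or sim_size % bin_b:
        raise ValueError("binning factors must divide the simulation grid size")

    planes = [] if sample is None else list(sample.planes)
    for z, mask in planes:
        if mask.values.shape != (sim_size, sim_size) or not np.isclose(
            mask.spacing, dx, rtol=1e-6
        ):
            raise ValueError(
                f"sample plane at z = {z:.3e} m has grid "
                f"{mask.values.shape}/{mask.spacing:.3e} m, inconsistent with the "
                f"simulation grid {sim_size}^2/{dx:.3e} m"
            )
    # light traverses planes from the farthest (largest f) toward the objective
    planes = sorted(planes, key=lambda p: p[0], reverse=True)
    planes = [(z, mask.values.astype(dtype)) for z, mask in planes]
    z_first = planes[0][0] if planes else 0.0

    coh_width = (
        config.wavelength * config.source_to_sample_distance / config.source_spot_diameter
    )
    if illumination == "auto":
        illumination = "direct" if coh_width < dx else "propagated"
    if illumination not in ("direct", "propagated"):
        raise ValueError(f"unknown illumination mode {illumination!r}")
    source_mask = None
    if illumination == "propagated":
        radius = config.source_spot_diameter / 2
        if radius < sim_size * dx / 2:
            c = centered_coords(sim_size, dx)
            source_mask = c[:, None] ** 2 + c[None, :] ** 2 <= radius**2
    return dict(
        config=config, dx=dx, sim_size=sim_size, bin_a=bin_a, bin_b=bin_b,
        planes=planes, z_first=z_first, illumination=illumination,
        source_mask=source_mask, dtype=dtype,
    )


def _simulate_one(prep: dict, seed: int, frame_index: int) -> tuple[np.ndarray, np.ndarray]:
    config: OpticalConfig = prep["config"]
    n, dx, dtype = prep["sim_size"], prep["dx"], prep["dtype"]
    rng = np.random.default_rng([seed, frame_index])
    amp = (
        rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    ).astype(dtype) / np.sqrt(2)
    if prep["illumination"] == "direct":
        field = ComplexField(amp, dx, config.wavelength, z=prep["z_first"])
    else:
        if prep["source_mask"] is not None:
            amp = amp * prep["source_mask"]
        field = ComplexField(
            amp, dx, config.wavelength,
            z=prep["z_first"] + config.source_to_sample_distance,
        )
        field = propagate(field, config.source_to_sample_distance)

    for z, mask_vals in prep["planes"]:
        field = propagate(field, field.z - z)
        field = replace(field, amplitude=field.amplitude * mask_vals)
    field = propagate(field, field.z)  # to the focal plane (z = 0)

    spectrum = _cfft2(field.amplitude)
    spectrum *= _pupil_mask(n, dx, config)

    intensity_b = periodic_flip(np.abs(spectrum) ** 2)
    image = _cifft2(spectrum)
    intensity_a = periodic_flip(np.abs(image) ** 2)

    i_a = block_bin(intensity_a.astype(np.float64), prep["bin_a"])
    i_b = block_bin(intensity_b.astype(np.float64), prep["bin_b"])
    return i_a, i_b


def simulate_arrays(
    sample: ThickSample | None,
    config: OpticalConfig,
    n_frames: int,
    seed: int,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n_frames`` paired frames; returns (I_a, I_b, coords_a, coords_b)
    with stacks shaped (N, n, n).  Frames are indexed from the master seed so a
    stack is reproducible and restartable."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    prep = _prepare_simulation(
        sample, config, kwargs.get("detectors"),
        sim_size=kwargs.get("sim_size", 512), spacing=kwargs.get("spacing"),
        bin_a=kwargs.get("bin_a", 4), bin_b=kwargs.get("bin_b", 16),
        illumination=kwargs.get("illumination", "auto"),
        dtype=kwargs.get("dtype", np.complex64),
    )
    n = prep["sim_size"]
    ia = np.empty((n_frames, n // prep["bin_a"], n // prep["bin_a"]), dtype=np.float32)
    ib = np.empty((n_frames, n // prep["bin_b"], n // prep["bin_b"]), dtype=np.float32)
    for k in range(n_frames):
        ia[k], ib[k] = _simulate_one(prep, seed, k)
    ca, cb = detector_coords(config, n, prep["dx"], prep["bin_a"], prep["bin_b"])
    return ia, ib, ca, cb
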