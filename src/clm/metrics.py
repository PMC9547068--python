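"""Design formulas: resolution, depth of field, viewpoint multiplicity.

Conventions (all lengths in meters unless noted):

* diffraction-limited resolution cell  Dx0 = 0.61 lambda / NA0;
* refocusing range (DOF extension) of correlation light-field microscopy at
  object detail size a:  3.3 a^2 / lambda  — quadratic in a and independent
  of the numerical aperture;
* axial resolution at detail size a (any technique):  a / NA0;
* viewpoint multiplicity a / Dx0 = number of sample-defined resolution cells
  across the objective pupil;
* visibility V = (peak - trough) / (peak + trough) of a slit profile, with
  the 10 % threshold generalizing the Rayleigh criterion to defocused images.

Note the reference instrument quotes a measured resolution cell
delta = 1.6 µm at NA0 = 0.23, lambda = 532 nm, while 0.61 lambda/NA0 gives
1.41 µm; the formulas here implement the analytic expression and make no
attempt to reconcile the measured value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import OpticalConfig

__all__ = [
    "TradeoffRow",
    "VisibilityReport",
    "diffraction_limit",
    "clm_refocus_range",
    "axial_resolution",
    "lens_resolution_cell",
    "viewpoint_multiplicity",
    "n_refocusable_planes",
    "magnification",
    "viewpoint_angle",
    "visibility",
    "tradeoff_table",
    "dof_extension_factor",
    "refocusable_planes_in_volume",
]


def _check_na(na: float) -> None:
    if not 0.0 < na < 1.0:
        raise ValueError(f"numerical aperture must lie in (0, 1), got {na}")


def diffraction_limit(wavelength: float, na: float) -> float:
    """Diffraction-limited resolution cell Dx0 = 0.61 lambda / NA."""
    _check_na(na)
    return 0.61 * wavelength / na


def clm_refocus_range(a: float, wavelength: float) -> float:
    """DOF extension (refocusing range) at detail size a: 3.3 a^2 / lambda.

    Quadratic in the detail size and independent of the numerical aperture;
    warns when a is below the wavelength scale where the formula loses
    meaning."""
    if a < wavelength:
        warnings.warn("detail size below the diffraction scale; refocus range formula unreliable")
    return 3.3 * a**2 / wavelength


def axial_resolution(a: float, na: float) -> float:
    """Axial resolution (DOF of one refocused plane) at detail size a: a / NA."""
    _check_na(na)
    return a / na


def lens_resolution_cell(a: float, wavelength: float, f_o: float) -> float:
    """Resolution cell on the objective-lens plane when the sample (size a)
    acts as the aperture: 1.22 lambda f_O / a."""
    if a <= 0:
        raise ValueError("detail size must be > 0")
    return 1.22 * wavelength * f_o / a


def viewpoint_multiplicity(a: float, wavelength: float, na: float) -> float:
    """Viewpoints per transverse direction, a / Dx0 (real-valued; caller
    rounds).  Details below the resolution cell clamp to 1 with a warning."""
    dx0 = diffraction_limit(wavelength, na)
    if a < dx0:
        warnings.warn("detail size below the resolution cell; clamping multiplicity to 1")
        return 1.0
    return a / dx0


def n_refocusable_planes(a: float, wavelength: float, na: float) -> tuple[float, float]:
    """Number of independently refocusable axial planes at detail size a.

    Returns the exact ratio (3.3 a^2/lambda) / (a/NA) and its
    2 a / Dx0 approximation (they agree to 3.3 * 0.61 / 2 = 1.0065)."""
    exact = clm_refocus_range(a, wavelength) / axial_resolution(a, na)
    approx = 2.0 * a / diffraction_limit(wavelength, na)
    return exact, approx


def magnification(f_t: float, f_o: float) -> float:
    """Natural microscope magnification M = f_T / f_O."""
    if f_o <= 0:
        raise ValueError("objective focal length must be > 0")
    return f_t / f_o


def viewpoint_angle(rho_o: float, f_o: float) -> float:
    """Signed viewpoint angle (degrees) of the lens point rho_o w.r.t. the
    optical axis: atan(rho_o / f_O)."""
    if f_o <= 0:
        raise ValueError("objective focal length must be > 0")
    return math.degrees(math.atan(rho_o / f_o))


@dataclass(frozen=True)
class VisibilityReport:
    """Peak/trough analysis of a multi-slit profile."""

    visibility: float | None
    peak_positions: tuple[float, ...]
    trough_positions: tuple[float, ...]
    resolved: bool


def visibility(
    profile: np.ndarray,
    expected_positions: np.ndarray,
    coords: np.ndarray | None = None,
    threshold: float = 0.10,
) -> VisibilityReport:
    """Slit-profile visibility against the resolvability threshold.

    ``profile`` is the image intensity averaged along the slit axis (and
    typically normalized to its maximum); ``expected_positions`` are the known
    slit centers in the same coordinates as ``coords`` (pixel index if coords
    is None).  Peaks are the local maxima nearest each expected center (within
    half the minimum center spacing); troughs are the profile minima between
    adjacent peaks.  V = (mean peak - mean trough) / (mean peak + mean trough);
    if any expected peak cannot be located the profile is unresolved and V is
    undefined (None).
    """
    profile = np.asarray(profile, dtype=float)
    if coords is None:
        coords = np.arange(profile.size, dtype=float)
    coords = np.asarray(coords, dtype=float)
    expected = np.sort(np.asarray(expected_positions, dtype=float))
    if expected.size < 2:
        raise ValueError("need at least two expected slit positions")
    tol = np.min(np.diff(expected)) / 2.0

    peak_idx, _ = signal.find_peaks(profile)
    peaks = []
    for pos in expected:
        if peak_idx.size == 0:
            return VisibilityReport(None, (), (), False)
        cand = peak_idx[np.argmin(np.abs(coords[peak_idx] - pos))]
        if abs(coords[cand] - pos) > tol:
            return VisibilityReport(None, (), (), False)
        peaks.append(cand)
    peaks = sorted(set(peaks))
    if len(peaks) < expected.size:
        return VisibilityReport(None, (), (), False)

    troughs = []
    for i, j in zip(peaks, peaks[1:]):
        troughs.append(i + int(np.argmin(profile[i : j + 1])))
    peak_val = float(np.mean(profile[peaks]))
    trough_val = float(np.mean(profile[troughs]))
    vis = (peak_val - trough_val) / (peak_val + trough_val)
    return VisibilityReport(
        visibility=vis,
        peak_positions=tuple(float(coords[i]) for i in peaks),
        trough_positions=tuple(float(coords[i]) for i in troughs),
        resolved=vis >= threshold,
    )


@dataclass(frozen=True)
class TradeoffRow:
    """One technique's resolution/DOF budget at detail size a."""

    technique: str  # standard | lightfield | clm
    resolution_limit: float
    dof_at_limit: float
    dof_extension: float
    axial_res: float
    viewpoints: float
    n_u: int | None = None

    def __post_init__(self) -> None:
        for name in ("resolution_limit", "dof_at_limit", "dof_extension", "axial_res"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_u is not None and self.n_u < 1:
            raise ValueError("N_u must be >= 1")


def tradeoff_table(config: OpticalConfig, a: float, n_u: int) -> list[TradeoffRow]:
    """Three-technique comparison (standard / light-field / CLM) at detail
    size ``a`` with ``n_u`` directional cells for the light-field row."""
    if n_u < 1:
        raise ValueError("N_u must be >= 1")
    lam, na = config.wavelength, config.numerical_aperture
    dx0 = diffraction_limit(lam, na)
    ax = axial_resolution(a, na)
    return [
        TradeoffRow("standard", dx0, dx0 / na, a / na, ax, 1.0),
        TradeoffRow("lightfield", n_u * dx0, n_u**2 * dx0 / na, n_u * a / na, ax, float(n_u), n_u),
        TradeoffRow("clm", dx0, dx0 / na, clm_refocus_range(a, lam), ax, a / dx0),
    ]


def dof_extension_factor(axial_span: float, d: float, na: float) -> float:
    """Observed DOF gain of a refocused two-plane acquisition: the axial span
    covered, divided by the full-range circle-of-confusion DOF 2 d / NA at
    detail size d (the center-to-center slit distance)."""
    _check_na(na)
    if axial_span <= 0 or d <= 0:
        raise ValueError("axial_span and d must be > 0")
    return axial_span / (2.0 * d / na)


def refocusable_planes_in_volume(
    depth: float, wavelength: float, na: float, n_steps: int = 4096
) -> float:
    """Distinguishable-plane count across a volume of the given depth,
    centered on the focal plane.

    At defocus z the smallest refocusable detail is a(z) with
    3.3 a^2/lambda = 2 |z|, clamped below at Dx0; the local plane thickness is
    a(z)/NA, and the count is the integral of NA / a(z) over z.  The clamping
    convention is explicit here because no standard one exists; the result is
    indicative, not a calibrated quantity.
    """
    _check_na(na)
    dx0 = diffraction_limit(wavelength, na)
    z = np.linspace(-depth / 2, depth / 2, n_steps)
    a_z = np.maximum(np.sqrt(2.0 * np.abs(z) * wavelength / 3.3), dx0)
    return float(np.trapezoid(na / a_z, z))
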