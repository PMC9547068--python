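"""Instrument description: optics and detector geometry.

The defaults reproduce the reference two-arm plenoptic microscope: a 532 nm
pseudo-thermal source (laser + rotating ground-glass diffuser, 8 mm spot,
sample 10 mm downstream), an objective of focal length 30 mm with effective
numerical aperture 0.23, a 125 mm tube lens imaging the sample onto the
spatial detector D_a (magnification M = f_T/f_O), and a 150 mm relay lens
imaging the objective pupil onto the angular detector D_b (magnification
M_L = 0.31).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

__all__ = ["OpticalConfig", "DetectorSpec"]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class OpticalConfig:
    """All instrument parameters of the two-arm correlation microscope.

    Lengths are in meters.  ``pupil_radius`` defaults to ``NA0 * f_O``
    (paraxial aperture stop matching the stated numerical aperture).
    ``numerical_aperture`` is an independent input: it is *not* derived from
    the source spot geometry.
    """

    wavelength: float = 532e-9
    numerical_aperture: float = 0.23
    objective_focal: float = 30e-3
    tube_focal: float = 125e-3
    relay_focal: float = 150e-3
    lens_arm_magnification: float = 0.31
    pupil_radius: float | None = None
    source_spot_diameter: float = 8e-3
    source_to_sample_distance: float = 10e-3
    coherence_time: float = 92.3e-6  # metadata only; one frame = one tau

    def __post_init__(self) -> None:
        for name in (
            "wavelength",
            "objective_focal",
            "tube_focal",
            "relay_focal",
            "lens_arm_magnification",
            "source_spot_diameter",
            "source_to_sample_distance",
            "coherence_time",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError(
                f"numerical_aperture must lie in (0, 1), got {self.numerical_aperture}"
            )
        if self.pupil_radius is None:
            object.__setattr__(
                self, "pupil_radius", self.numerical_aperture * self.objective_focal
            )
        if self.pupil_radius <= 0:
            raise ValueError("pupil_radius must be > 0")

    @property
    def magnification(self) -> float:
        """Natural microscope magnification M = f_T / f_O."""
        return self.tube_focal / self.objective_focal

    @property
    def diffraction_limit(self) -> float:
        """Diffraction-limited resolution cell 0.61 lambda / NA0 (m)."""
        return 0.61 * self.wavelength / self.numerical_aperture

    @property
    def band_limit_spacing(self) -> float:
        """Largest sample-plane grid spacing resolving the aperture, lambda/(2 NA0)."""
        return self.wavelength / (2.0 * self.numerical_aperture)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "OpticalConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class DetectorSpec:
    """Pixelated sensor geometry: pitch (m), grid shape, hardware binning."""

    pixel_pitch: float = 6.5e-6
    shape: tuple[int, int] = (128, 128)
    binning: int = 1

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if len(self.shape) != 2 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be two positive integers, got {self.shape}")
        if self.binning < 1 or int(self.binning) != self.binning:
            raise ValueError("binning must be a positive integer")
        object.__setattr__(self, "shape", (int(self.shape[0]), int(self.shape[1])))

    @property
    def effective_pitch(self) -> float:
        """Pitch after binning (m)."""
        return self.pixel_pitch * self.binning

    def to_dict(self) -> dict[str, Any]:
        return {"pixel_pitch": self.pixel_pitch, "shape": list(self.shape), "binning": self.binning}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DetectorSpec":
        return cls(
            pixel_pitch=d["pixel_pitch"], shape=tuple(d["shape"]), binning=d.get("binning", 1)
        )
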