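"""On-disk formats: paired frame stacks (multi-page TIFF + JSON sidecar),
correlation tensors (HDF5), and run configuration (YAML).

Frames are stored one page per frame, one file per arm, as 16-bit integers
scaled to full range (camera-like), with the scale recorded in the sidecar;
already-integer data are stored verbatim so the round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import tifffile
import yaml

from .config import DetectorSpec, OpticalConfig
from .correlation import CorrelationTensor, FrameStack
from .phantoms import TransmissionMask

__all__ = [
    "RunConfig",
    "write_frame_stack",
    "read_frame_stack",
    "save_gamma",
    "load_gamma",
    "write_mask",
    "config_hash",
]


def write_mask(mask: TransmissionMask, path: str | Path) -> Path:
    """Export a transmission mask as a float32 TIFF with its pixel spacing
    recorded in the image description."""
    path = Path(path)
    tifffile.imwrite(
        path,
        mask.values.astype(np.float32),
        description=json.dumps({"spacing_m": mask.spacing, "fov_m": mask.fov}),
    )
    return path

_SIDECAR_KEYS = ("n_frames", "coords_a", "coords_b", "scale_a", "scale_b")


def config_hash(config: OpticalConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclasses.dataclass
class RunConfig:
    """One reproducible acquisition: instrument + sample + run parameters."""

    optics: OpticalConfig = dataclasses.field(default_factory=OpticalConfig)
    sample: dict[str, Any] = dataclasses.field(default_factory=dict)
    frames: int = 2000
    seed: int = 0
    estimator: str = "plain"
    sim_size: int = 512
    bin_a: int = 4
    bin_b: int = 16
    output: str = "clm_run"

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["optics"] = self.optics.to_dict()
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["optics"] = OpticalConfig.from_dict(doc.get("optics", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in known})


def _encode_arm(frames: np.ndarray) -> tuple[np.ndarray, float]:
    if np.issubdtype(frames.dtype, np.integer):
        return frames.astype(np.uint16), 1.0
    peak = float(frames.max())
    scale = peak / 65535.0 if peak > 0 else 1.0
    return np.round(frames / scale).astype(np.uint16), scale


def write_frame_stack(
    stack: FrameStack,
    path: str | Path,
    config: OpticalConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write a paired stack to ``path/`` as arm_a.tif, arm_b.tif, stack.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    enc_a, scale_a = _encode_arm(np.asarray(stack.frames_a))
    enc_b, scale_b = _encode_arm(np.asarray(stack.frames_b))
    tifffile.imwrite(path / "arm_a.tif", enc_a)
    tifffile.imwrite(path / "arm_b.tif", enc_b)
    sidecar = {
        "n_frames": stack.n_frames,
        "coords_a": np.asarray(stack.coords_a).tolist(),
        "coords_b": np.asarray(stack.coords_b).tolist(),
        "scale_a": scale_a,
        "scale_b": scale_b,
    }
    if config is not None:
        sidecar["optics"] = config.to_dict()
        sidecar["config_hash"] = config_hash(config)
    if seed is not None:
        sidecar["seed"] = seed
    (path / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_frame_stack(path: str | Path) -> FrameStack:
    """Read a paired stack written by :func:`write_frame_stack`."""
    path = Path(path)
    sidecar_path = path / "stack.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path}; required keys: {', '.join(_SIDECAR_KEYS)}"
        )
    sidecar = json.loads(sidecar_path.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise KeyError(f"sidecar {sidecar_path} lacks required keys: {', '.join(missing)}")
    frames_a = tifffile.imread(path / "arm_a.tif")
    frames_b = tifffile.imread(path / "arm_b.tif")
    if frames_a.ndim == 2:
        frames_a = frames_a[None]
    if frames_b.ndim == 2:
        frames_b = frames_b[None]
    if frames_a.shape[0] != frames_b.shape[0]:
        raise ValueError(
            f"arm page counts differ: {frames_a.shape[0]} (a) vs {frames_b.shape[0]} (b)"
        )
    if frames_a.shape[0] != sidecar["n_frames"]:
        raise ValueError("page count disagrees with the sidecar n_frames")
    sa, sb = sidecar["scale_a"], sidecar["scale_b"]
    return FrameStack(
        frames_a=frames_a if sa == 1.0 else frames_a * sa,
        frames_b=frames_b if sb == 1.0 else frames_b * sb,
        coords_a=np.asarray(sidecar["coords_a"]),
        coords_b=np.asarray(sidecar["coords_b"]),
    )


def save_gamma(
    tensor: CorrelationTensor, path: str | Path, config: OpticalConfig | None = None
) -> Path:
    """Persist a correlation tensor as HDF5 (values + four coordinate axes)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("gamma", data=tensor.values, compression="gzip", compression_opts=1)
        h5.create_dataset("x_a", data=tensor.coords_a)
        h5.create_dataset("y_a", data=tensor.coords_a)
        h5.create_dataset("x_b", data=tensor.coords_b)
        h5.create_dataset("y_b", data=tensor.coords_b)
        h5.attrs["estimator"] = tensor.estimator
        h5.attrs["n_frames"] = tensor.n_frames
        if config is not None:
            h5.attrs["config_hash"] = config_hash(config)
            h5.attrs["config_json"] = json.dumps(config.to_dict())
    return path


def load_gamma(path: str | Path, config: OpticalConfig | None = None) -> CorrelationTensor:
    """Load a correlation tensor; warns if the stored config hash disagrees
    with the supplied config."""
    try:
        with h5py.File(path, "r") as h5:
            values = h5["gamma"][()]
            coords_a = h5["x_a"][()]
            coords_b = h5["x_b"][()]
            estimator = h5.attrs.get("estimator", "plain")
            n_frames = int(h5.attrs.get("n_frames", 0))
            stored_hash = h5.attrs.get("config_hash")
    except OSError as exc:
        raise OSError(f"cannot read correlation container {path}: {exc}") from exc
    if config is not None and stored_hash is not None and stored_hash != config_hash(config):
        import warnings

        warnings.warn(
            f"optical config hash mismatch for {path}: stored {stored_hash}, "
            f"supplied {config_hash(config)}"
        )
    return CorrelationTensor(
        values=values,
        coords_a=coords_a,
        coords_b=coords_b,
        estimator=str(estimator),
        n_frames=n_frames,
    )
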