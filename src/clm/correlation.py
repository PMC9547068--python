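"""Estimation of the 4D intensity-fluctuation correlation function.

Given N paired frames, the plain estimator is the empirical covariance

    Gamma(rho_a, rho_b) = (1/N) sum_j [I_a_j(rho_a) - <I_a>] [I_b_j(rho_b) - <I_b>]

over frames, computed in a single pass from sum accumulators so memory stays
O(tensor) rather than O(N * tensor).  The differential estimator additionally
subtracts the component of the arm-b fluctuation explained by the *total*
arm-a intensity (differential ghost-imaging correction), with the per-pixel
coefficient K(rho_b) chosen to minimize the estimator variance:

    K(rho_b) = <dI_b(rho_b) dI_a_tot> / <(dI_a_tot)^2>
    Gamma~(rho_a, rho_b) = Gamma(rho_a, rho_b) - K(rho_b) <dI_a(rho_a) dI_a_tot>.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from ._grids import block_bin, block_bin_coords

__all__ = [
    "FrameStack",
    "CorrelationTensor",
    "DifferentialParams",
    "estimate_gamma",
    "optimal_k",
    "estimate_gamma_differential",
]


@dataclass(frozen=True)
class FrameStack:
    """N paired frames with square per-arm grids and physical coordinates."""

    frames_a: np.ndarray  # (N, na, na)
    frames_b: np.ndarray  # (N, nb, nb)
    coords_a: np.ndarray  # (na,) pixel centers on D_a, both axes (m)
    coords_b: np.ndarray  # (nb,)

    def __post_init__(self) -> None:
        fa, fb = np.asarray(self.frames_a), np.asarray(self.frames_b)
        if fa.ndim != 3 or fb.ndim != 3:
            raise ValueError("frame stacks must be (N, rows, cols)")
        if fa.shape[0] != fb.shape[0]:
            raise ValueError(
                f"arms hold different frame counts: {fa.shape[0]} vs {fb.shape[0]}"
            )
        if fa.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if fa.shape[1] != len(self.coords_a) or fb.shape[1] != len(self.coords_b):
            raise ValueError("coordinate vectors inconsistent with frame shapes")
        object.__setattr__(self, "frames_a", fa)
        object.__setattr__(self, "frames_b", fb)

    @property
    def n_frames(self) -> int:
        return self.frames_a.shape[0]

    def subset(self, index) -> "FrameStack":
        """Select a sub-stack of frames (slice or index array)."""
        return replace(self, frames_a=self.frames_a[index], frames_b=self.frames_b[index])

    def binned(self, factor_a: int = 1, factor_b: int = 1) -> "FrameStack":
        """Block-sum binning applied before correlation (hardware-binning model)."""
        return FrameStack(
            frames_a=block_bin(self.frames_a, factor_a),
            frames_b=block_bin(self.frames_b, factor_b),
            coords_a=block_bin_coords(np.asarray(self.coords_a), factor_a),
            coords_b=block_bin_coords(np.asarray(self.coords_b), factor_b),
        )


@dataclass(frozen=True)
class CorrelationTensor:
    """Binned 4D correlation Gamma indexed (y_a, x_a, y_b, x_b)."""

    values: np.ndarray
    coords_a: np.ndarray
    coords_b: np.ndarray
    estimator: str = "plain"  # plain | differential | oracle:geometric
    n_frames: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 4:
            raise ValueError("correlation tensor must be 4D")
        if not np.all(np.isfinite(v)):
            raise ValueError("correlation tensor contains non-finite values")
        for c in (self.coords_a, self.coords_b):
            if np.any(np.diff(np.asarray(c)) <= 0):
                raise ValueError("coordinate vectors must be strictly increasing")
        if v.shape[:2] != (len(self.coords_a),) * 2 or v.shape[2:] != (len(self.coords_b),) * 2:
            raise ValueError("tensor shape inconsistent with coordinates")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def correlation_image(self) -> np.ndarray:
        """Arm-a image summed over all viewpoints, sum_b Gamma(rho_a, .)."""
        return self.values.sum(axis=(2, 3))


@dataclass(frozen=True)
class DifferentialParams:
    """Variance-minimizing coefficient map and the total-intensity series."""

    k_map: np.ndarray  # (nb, nb) over rho_b
    delta_i_tot: np.ndarray  # (N,) fluctuation of the total arm-a intensity

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.k_map)):
            raise ValueError("K map contains non-finite values")


def _moments(stack: FrameStack, chunk: int = 256):
    """Single-pass accumulation of all first/second moments needed by both
    estimators.  Cross term via chunked matrix products (BLAS)."""
    n = stack.n_frames
    na = stack.frames_a.shape[1]
    nb = stack.frames_b.shape[1]
    pa, pb = na * na, nb * nb
    sum_a = np.zeros(pa)
    sum_b = np.zeros(pb)
    cross = np.zeros((pa, pb))
    sum_at = np.zeros(pa)  # sum_j I_a_j * T_j
    sum_bt = np.zeros(pb)
    sum_t = 0.0
    sum_t2 = 0.0
    tot = np.empty(n)
    for lo in range(0, n, chunk):
        a = stack.frames_a[lo : lo + chunk].reshape(-1, pa).astype(np.float64)
        b = stack.frames_b[lo : lo + chunk].reshape(-1, pb).astype(np.float64)
        t = a.sum(axis=1)
        tot[lo : lo + a.shape[0]] = t
        sum_a += a.sum(axis=0)
        sum_b += b.sum(axis=0)
        cross += a.T @ b
        sum_at += t @ a
        sum_bt += t @ b
        sum_t += t.sum()
        sum_t2 += t @ t
    return dict(
        n=n, na=na, nb=nb,
        mean_a=sum_a / n, mean_b=sum_b / n,
        cov_ab=cross / n - np.outer(sum_a / n, sum_b / n),
        cov_at=sum_at / n - (sum_a / n) * (sum_t / n),
        cov_bt=sum_bt / n - (sum_b / n) * (sum_t / n),
        var_t=sum_t2 / n - (sum_t / n) ** 2,
        delta_t=tot - sum_t / n,
    )


def estimate_gamma(stack: FrameStack, chunk: int = 256) -> CorrelationTensor:
    """Plain covariance estimator of the 4D correlation function (1/N norm)."""
    m = _moments(stack, chunk)
    values = m["cov_ab"].reshape(m["na"], m["na"], m["nb"], m["nb"])
    return CorrelationTensor(
        values=values,
        coords_a=np.asarray(stack.coords_a, dtype=float),
        coords_b=np.asarray(stack.coords_b, dtype=float),
        estimator="plain",
        n_frames=m["n"],
    )


def optimal_k(stack: FrameStack, chunk: int = 256) -> DifferentialParams:
    """Variance-minimizing coefficient K(rho_b) from empirical moments."""
    m = _moments(stack, chunk)
    if m["var_t"] <= 0:
        raise ValueError("total arm-a intensity has zero variance (degenerate stack)")
    k = (m["cov_bt"] / m["var_t"]).reshape(m["nb"], m["nb"])
    return DifferentialParams(k_map=k, delta_i_tot=m["delta_t"])


def estimate_gamma_differential(stack: FrameStack, chunk: int = 256) -> CorrelationTensor:
    """Differential (noise-suppressed) estimator: plain covariance minus the
    rank-1 spurious self-correlation with the total arm-a intensity."""
    m = _moments(stack, chunk)
    if m["var_t"] <= 0:
        raise ValueError("total arm-a intensity has zero variance (degenerate stack)")
    k = m["cov_bt"] / m["var_t"]
    values = m["cov_ab"] - np.outer(m["cov_at"], k)
    return CorrelationTensor(
        values=values.reshape(m["na"], m["na"], m["nb"], m["nb"]),
        coords_a=np.asarray(stack.coords_a, dtype=float),
        coords_b=np.asarray(stack.coords_b, dtype=float),
        estimator="differential",
        n_frames=m["n"],
    )
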