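"""Border-ownership map representation and elementary operations.

A border-ownership (BO) map is a real tensor ``b[y, x, l]`` over image
locations and ``L`` discrete directions.  The unit vector of direction
``l`` is ``u_l = (cos a_l, sin a_l)`` with ``a_l = 2*pi*l/L`` measured
counter-clockwise from +x in display coordinates (y up); it points from a
boundary *into* the object that owns it, and the boundary itself runs
perpendicular to ``u_l``.  Positive and negative BO values carry the same
meaning — every cost term consumes ``b**2`` — so maps are compared through
their squares.

The grid of BO sites coincides with the image pixel grid (one site per
pixel, at the pixel center).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "DirectionSet",
    "random_init",
    "smooth_bo",
    "bo_distance",
    "save_bo",
    "load_bo",
    "gaussian_kernel_1d",
    "angular_smoothing_matrix",
    "spatial_smooth",
]


@dataclass(frozen=True)
class DirectionSet:
    """``L`` equally spaced discrete directions; ``L`` must be divisible by 4.

    Divisibility by 4 is required by the opposite-direction pairing (index
    offset L/2) and the perpendicular rotation (offset L/4) used throughout
    the cost functional.
    """

    L: int = 12

    def __post_init__(self) -> None:
        if self.L % 4 != 0 or self.L < 4:
            raise ValueError(f"L must be a positive multiple of 4, got {self.L}")

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.L) / self.L

    @property
    def unit_vectors(self) -> np.ndarray:
        """(L, 2) array of (ux, uy) components in display coordinates (y up)."""
        a = self.angles
        return np.stack([np.cos(a), np.sin(a)], axis=1)

    @property
    def unit_vectors_array(self) -> np.ndarray:
        """(L, 2) array of (dx, dy_row) offsets in array coordinates (row down)."""
        a = self.angles
        return np.stack([np.cos(a), -np.sin(a)], axis=1)

    def wrap(self, l) -> np.ndarray:
        return np.mod(l, self.L)


def random_init(dims: tuple[int, int, int], seed: int) -> np.ndarray:
    """Initial BO map: i.i.d. uniform values in [0.01, 0.02].

    Starting from a small random map rather than from zero avoids the
    stationary saddle point at the origin (every cost term is at least
    quadratic in b, so the gradient vanishes identically at b = 0).
    """
    rng = np.random.default_rng(seed)
    return rng.uniform(0.01, 0.02, size=dims)


@lru_cache(maxsize=128)
def gaussian_kernel_1d(sigma: float, normalize: bool = True) -> np.ndarray:
    """Discrete 1-D Gaussian, truncated at radius ceil(3*sigma), odd support."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(np.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    if normalize:
        k /= k.sum()
    else:
        k /= np.sqrt(2.0 * np.pi) * sigma
    return k


@lru_cache(maxsize=128)
def angular_smoothing_matrix(L: int, sigma_sa: float) -> np.ndarray:
    """Circulant matrix of the circular Gaussian over direction offsets.

    The kernel is defined on offsets j in [-(L/2 - 1), L/2] and normalized
    to unit sum; wrapping makes it circularly symmetric, so the matrix is
    symmetric (the smoothing operator is self-adjoint).
    """
    if sigma_sa <= 0:
        raise ValueError(f"sigma_sa must be positive, got {sigma_sa}")
    j = np.arange(-(L // 2 - 1), L // 2 + 1, dtype=float)
    w = np.exp(-(j**2) / (2.0 * sigma_sa**2))
    w /= w.sum()
    m = np.zeros((L, L))
    for jj, wj in zip(j.astype(int), w):
        for l in range(L):
            m[l, (l + jj) % L] += wj
    return m


def spatial_smooth(arr: np.ndarray, sigma: float, axes=(0, 1), mode="constant") -> np.ndarray:
    """Separable Gaussian filtering over the spatial axes (zero padding by default)."""
    k = gaussian_kernel_1d(float(sigma))
    out = arr
    for ax in axes:
        out = correlate1d(out, k, axis=ax, mode=mode, cval=0.0)
    return out


def smooth_bo(b: np.ndarray, sigma_sa: float, sigma_sx: float) -> np.ndarray:
    """Smooth a BO map in angle then in space.

    Angular smoothing is a circular Gaussian convolution over the direction
    index; spatial smoothing is a separable Gaussian with zero padding (no
    ownership exists outside the canvas).  Both kernels sum to one, so a
    constant map is unchanged.  The operator is linear and self-adjoint,
    which the cost-gradient computation relies on.
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 3:
        raise ValueError("BO map must have shape (height, width, L)")
    m = angular_smoothing_matrix(b.shape[2], float(sigma_sa))
    c = np.tensordot(b, m, axes=([2], [1]))
    return spatial_smooth(c, sigma_sx)


def bo_distance(b1: np.ndarray, b2: np.ndarray) -> float:
    """Mean absolute difference of squared BO values.

    A sign-blind dissimilarity: zero iff ``b1**2 == b2**2`` everywhere, so
    maps differing only by sign flips are identified (they carry the same
    boundary-ownership meaning).  It is a metric on squared maps.
    """
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if b1.shape != b2.shape:
        raise ValueError(f"shape mismatch: {b1.shape} vs {b2.shape}")
    return float(np.abs(b1**2 - b2**2).mean())


def save_bo(b: np.ndarray, cost: float, path: str, meta: dict | None = None) -> None:
    """Write a BO map to a ``.bo`` file: one JSON header line + float64 payload."""
    b = np.ascontiguousarray(b, dtype="<f8")
    header = {"shape": list(b.shape), "cost": float(cost), "dtype": "<f8"}
    if meta:
        header["meta"] = meta
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode("utf-8") + b"\n")
        fh.write(b.tobytes())


def load_bo(path: str) -> tuple[np.ndarray, float, dict]:
    """Read a ``.bo`` file; returns (map, cost, meta).  Lossless round trip."""
    with open(path, "rb") as fh:
        line = fh.readline()
        try:
            header = json.loads(line.decode("utf-8"))
            shape = tuple(int(s) for s in header["shape"])
            cost = float(header["cost"])
        except (ValueError, KeyError, UnicodeDecodeError) as exc:
            raise ValueError(f"{path}: corrupt .bo header") from exc
        payload = fh.read()
    expected = int(np.prod(shape)) * 8
    if len(payload) != expected:
        raise ValueError(
            f"{path}: payload length {len(payload)} does not match header dims {shape}"
        )
    arr = np.frombuffer(payload, dtype="<f8").reshape(shape).copy()
    return arr, cost, header.get("meta", {})
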