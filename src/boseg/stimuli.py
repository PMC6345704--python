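"""Synthetic gray-scale stimuli for figure-ground segregation experiments.

All generators produce binary {0, 1} rasters with solid, non-textured
regions: a two-region step-edge image, a centered square, a C-shaped object
(square with a rectangular mouth), and the Kanizsa illusory-square figure
built from four "pacman" inducers.  Images are plain 2-D float arrays of
shape (height, width) indexed ``[y, x]`` with y increasing downward.

Rasterization is deterministic and unantialiased: a pixel belongs to a
region iff its center does.  This keeps the oriented edge filters of the
cost functional well defined (clean step edges, no gray fringe).
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "KanizsaSpec",
    "make_edge_image",
    "make_square_image",
    "make_c_image",
    "make_kanizsa_image",
    "read_raster",
    "write_raster",
]


def _check_dims(width: int, height: int) -> None:
    if width <= 0 or height <= 0:
        raise ValueError(f"image dimensions must be positive, got {width}x{height}")


def make_edge_image(width: int = 20, height: int = 20) -> np.ndarray:
    """Two abutting uniform regions separated by a straight vertical edge.

    The left half is white (1), the right half black (0); the boundary sits
    at column ``width // 2``.  Both dimensions must be even so the halves
    are equal.
    """
    _check_dims(width, height)
    if width % 2 or height % 2:
        raise ValueError("edge image requires even width and height")
    img = np.zeros((height, width), dtype=float)
    img[:, : width // 2] = 1.0
    return img


def make_square_image(canvas: int = 20, side: int = 8) -> np.ndarray:
    """White ``side`` × ``side`` square centered on a black ``canvas`` × ``canvas`` field."""
    _check_dims(canvas, canvas)
    if side <= 0 or side >= canvas:
        raise ValueError(f"square side must be in (0, canvas), got side={side}, canvas={canvas}")
    img = np.zeros((canvas, canvas), dtype=float)
    off = (canvas - side) // 2
    img[off : off + side, off : off + side] = 1.0
    return img


def make_c_image(
    canvas: int = 24, outer: int = 12, mouth_width: int = 4, mouth_depth: int = 6
) -> np.ndarray:
    """C-shaped white object: a square with a rectangular notch cut from its right side.

    The notch (mouth) is ``mouth_depth`` pixels deep (in x) and
    ``mouth_width`` pixels tall (in y), vertically centered, so the figure
    has exactly one mirror-symmetry axis (horizontal, through the mouth).
    ``mouth_depth = 0`` degenerates to the plain square.
    """
    _check_dims(canvas, canvas)
    if outer >= canvas or outer <= 0:
        raise ValueError("outer side must be in (0, canvas)")
    if mouth_depth >= outer or mouth_width >= outer:
        raise ValueError("mouth must be strictly smaller than the outer square")
    if mouth_depth > 0 and mouth_width <= 0:
        raise ValueError("mouth with positive depth must have positive width")
    img = np.zeros((canvas, canvas), dtype=float)
    off = (canvas - outer) // 2
    img[off : off + outer, off : off + outer] = 1.0
    if mouth_depth > 0:
        my = (canvas - mouth_width) // 2
        img[my : my + mouth_width, off + outer - mouth_depth : off + outer] = 0.0
    return img


@dataclass(frozen=True)
class KanizsaSpec:
    """Geometry of a Kanizsa illusory-square stimulus.

    Four pacman inducers (black disks of radius ``r`` with the quadrant
    facing the canvas center removed) sit at the corners of an axis-aligned
    square of half-side ``h`` centered on the canvas.  The support ratio —
    visible edge length over total illusory-edge length — is ``r / h``.
    """

    canvas: int = 48
    h: float = 12.0
    r: float = 8.0

    @property
    def support_ratio(self) -> float:
        return self.r / self.h

    def validate(self) -> None:
        if not (0 < self.r <= self.h):
            raise ValueError(f"need 0 < r <= h, got r={self.r}, h={self.h}")
        if self.canvas < 2 * (self.h + self.r):
            raise ValueError("canvas too small: pacmans would be clipped")
        if 2 * self.r > 2 * self.h:  # pragma: no cover - implied by r <= h
            raise ValueError("pacmans overlap")


def make_kanizsa_image(spec: KanizsaSpec) -> np.ndarray:
    """Render a Kanizsa square: white background, four black pacman inducers.

    A pixel is black iff its center lies inside one of the disks and
    outside that disk's mouth quadrant.  Each mouth is the quadrant facing
    the canvas center, so the straight mouth edges are collinear with the
    illusory square's sides.
    """
    spec.validate()
    n = spec.canvas
    img = np.ones((n, n), dtype=float)
    yy, xx = np.mgrid[0:n, 0:n]
    # pixel centers; canvas center at (c, c)
    c = (n - 1) / 2.0
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            cx, cy = c + sx * spec.h, c + sy * spec.h
            dx, dy = xx - cx, yy - cy
            disk = dx * dx + dy * dy <= spec.r**2
            # mouth: the quadrant pointing back toward the canvas center
            mouth = (np.sign(dx) == -sx) & (np.sign(dy) == -sy) & (dx != 0) & (dy != 0)
            img[disk & ~mouth] = 0.0
    return img


def write_raster(raster: np.ndarray, path: str) -> None:
    """Write a [0, 1] gray-scale raster as an 8-bit PGM or PNG file."""
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2:
        raise ValueError("raster must be 2-D gray-scale")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("raster values must lie in [0, 1]")
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def read_raster(path: str) -> np.ndarray:
    """Read a gray-scale PGM/PNG raster, rescaled to floats in [0, 1].

    Color images are rejected; 8- and 16-bit depths are normalized by the
    dtype maximum so that a write/read round trip of any generated binary
    stimulus reproduces the pixel grid exactly.
    """
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a gray-scale image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / arr.max()
    return arr
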