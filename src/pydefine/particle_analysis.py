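"""Thresholding, binarization, particle labeling and shape measurement.

This is the measurement engine under both removal stages and the fiber
quantifier: images are thresholded at ``mean + k·SD``, converted to binary
masks, and 8-connected components ("particles") are measured for area (µm²),
perimeter (µm) and circularity ``4π·area/perimeter²``.

Perimeter is the weighted boundary-chain estimator: the outer boundary of a
particle is traced pixel-centre to pixel-centre (Moore neighbourhood), axis
steps contributing one pixel pitch and diagonal steps the diagonal pitch.
Under anisotropic pixels the pitches differ per axis, so both area and
perimeter stay correct in physical units.  Circularity is clipped to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from skimage import measure as _skmeasure

from .image_io import PixelGeometry

__all__ = [
    "BinaryMask",
    "Particle",
    "ParticleCriterion",
    "sd_threshold",
    "binarize",
    "label_particles",
    "circularity",
    "circularity_from_measurements",
    "subtract_mask",
]


@dataclass
class BinaryMask:
    """Boolean (y, x) grid plus the pixel geometry it was measured under."""

    on_pixels: np.ndarray
    geometry: PixelGeometry

    def __post_init__(self) -> None:
        self.on_pixels = np.asarray(self.on_pixels, dtype=bool)
        if self.on_pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.on_pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.count * self.geometry.pixel_area_um2


@dataclass
class ParticleCriterion:
    """One removal gate: remove particles with area ≥ ``min_area_um2`` AND
    circularity ≥ ``min_circularity``.

    The cleaning stage combines up to five such gates; a particle matching
    any one of them is removed.  Low-circularity gates need a large minimum
    area so that elongated but genuine fibers survive.
    """

    min_area_um2: float
    min_circularity: float

    def __post_init__(self) -> None:
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be positive")
        if not (0.0 <= self.min_circularity <= 1.0):
            raise ValueError("min_circularity must be in [0, 1]")

    def matches(self, particle: "Particle") -> bool:
        return (
            particle.area_um2 >= self.min_area_um2
            and particle.circularity >= self.min_circularity
        )


@dataclass
class Particle:
    """A labeled 8-connected component with physical shape measurements."""

    label: int
    coords: np.ndarray  # (n, 2) array of (y, x) pixel indices
    area_um2: float
    perimeter_um: float
    circularity: float

    @cached_property
    def pixel_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((int(y), int(x)) for y, x in self.coords)

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def contains(self, y: int, x: int) -> bool:
        return bool(np.any((self.coords[:, 0] == y) & (self.coords[:, 1] == x)))


def sd_threshold(pixels: np.ndarray, k: float) -> float:
    """``mean + k × population SD`` of all pixel intensities.

    The pipeline's universal threshold rule; ``k`` is the number of standard
    deviations above the mean.  For a constant image the SD is zero and the
    threshold equals the mean, which with the strict ``>`` comparison in
    :func:`binarize` yields an empty mask — blank slices are harmless no-ops.
    """
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("cannot threshold an empty image")
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(pixels.mean() + k * pixels.std())


def binarize(
    pixels: np.ndarray, threshold: float, geometry: PixelGeometry | None = None
) -> BinaryMask:
    """Strictly-greater binarization: on where ``intensity > threshold``."""
    if geometry is None:
        geometry = PixelGeometry(1.0, 1.0)
    return BinaryMask(np.asarray(pixels) > threshold, geometry)


# ---------------------------------------------------------------------------
# Boundary-chain perimeter

# Clockwise Moore neighbourhood starting north, as (dy, dx).
_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_OFFSET_INDEX = {off: i for i, off in enumerate(_OFFSETS)}


def _chain_perimeter(mask: np.ndarray, sx: float, sy: float) -> float:
    """Perimeter of the single 8-connected component in ``mask``.

    Moore boundary trace over pixel centres; horizontal steps weigh ``sx``,
    vertical ``sy``, diagonal ``hypot(sx, sy)``.  A single pixel is assigned
    the perimeter of its bounding rectangle, ``2(sx + sy)``.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return 0.0
    if ys.size == 1:
        return 2.0 * (sx + sy)
    m = np.pad(mask, 1)
    diag = math.hypot(sx, sy)
    step_len = {
        (0, 1): sx,
        (0, -1): sx,
        (1, 0): sy,
        (-1, 0): sy,
        (1, 1): diag,
        (1, -1): diag,
        (-1, 1): diag,
        (-1, -1): diag,
    }
    # Raster-first on-pixel: its W neighbour is off, a valid backtrack seed.
    start = (int(ys[0]) + 1, int(xs[0]) + 1)
    p = start
    b = (start[0], start[1] - 1)
    cum = 0.0
    # The walk (p, backtrack) is deterministic, so it must eventually revisit
    # a state; the distance between the two visits is one full boundary
    # cycle.  The artificial seed state may lie outside the cycle, hence the
    # memo rather than a compare-to-initial test.
    seen: dict[tuple, float] = {(p, b): 0.0}
    max_steps = 8 * ys.size + 8
    for _ in range(max_steps):
        i = _OFFSET_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        for k in range(1, 9):
            idx = (i + k) % 8
            c = (p[0] + _OFFSETS[idx][0], p[1] + _OFFSETS[idx][1])
            if m[c]:
                nxt = c
                prev_idx = (i + k - 1) % 8
                b = (p[0] + _OFFSETS[prev_idx][0], p[1] + _OFFSETS[prev_idx][1])
                break
        if nxt is None:  # isolated pixel; already handled above
            return 2.0 * (sx + sy)
        cum += step_len[(nxt[0] - p[0], nxt[1] - p[1])]
        p = nxt
        state = (p, b)
        if state in seen:
            return cum - seen[state]
        seen[state] = cum
    return cum  # unreachable for valid single-component input


def circularity_from_measurements(area: float, perimeter: float) -> float:
    """``min(1, 4π·area / perimeter²)`` with area and perimeter in the same
    unit system (both physical or both pixel-based)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def circularity(particle: Particle) -> float:
    """Shape circularity of a measured particle (1 = perfect circle)."""
    return particle.circularity


def label_particles(mask: BinaryMask) -> list[Particle]:
    """Measure the 8-connected components of a binary mask.

    Labels run 1..N in raster order of first pixel; every on-pixel belongs to
    exactly one particle.  Areas count on-pixels only (interior holes, being
    off-pixels, are excluded); the perimeter is the outer boundary chain.
    Single-pixel particles are maximally compact and take circularity 1 by
    convention, so they remain removable by high-circularity gates.
    """
    geom = mask.geometry
    labels = _skmeasure.label(mask.on_pixels, connectivity=2)
    particles: list[Particle] = []
    px_area = geom.pixel_area_um2
    for region in _skmeasure.regionprops(labels):
        n = int(region.area)
        area = n * px_area
        sub = labels[region.slice] == region.label
        perim = _chain_perimeter(sub, geom.x_um_per_px, geom.y_um_per_px)
        circ = 1.0 if n == 1 else circularity_from_measurements(area, perim)
        particles.append(
            Particle(
                label=int(region.label),
                coords=region.coords,
                area_um2=area,
                perimeter_um=perim,
                circularity=circ,
            )
        )
    return particles


def subtract_mask(pixels: np.ndarray, removal: BinaryMask) -> np.ndarray:
    """Zero every pixel under the removal mask; leave the rest untouched.

    The digital analogue of AND-ing an image with the inverse of a binary
    mask: removed structures go to zero rather than to a local background
    estimate, which keeps downstream area quantification conservative.
    """
    pixels = np.asarray(pixels)
    if pixels.shape != removal.on_pixels.shape:
        raise ValueError(
            f"image shape {pixels.shape} != mask shape {removal.on_pixels.shape}"
        )
    out = pixels.copy()
    out[removal.on_pixels] = 0
    return out
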