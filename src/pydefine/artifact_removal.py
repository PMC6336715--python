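"""The Clean Images pipeline: large-particle removal, autofluorescence
subtraction, maximum-intensity projection, and small-particle removal.

Large-particle removal and autofluorescence subtraction run per z-slice on
the stack; cleaning the stack rather than a pre-projected MIP is what lets a
fiber passing above or below an artifact survive — zeroing the artifact in
its own slices leaves the fiber's slices untouched, and the subsequent
projection recovers the fiber.  Small-particle removal runs once on the MIP
to clear residual speckle.

Every stage only ever zeroes pixels; no stage can increase an intensity or
invent signal, so the cleaned image is always a (pixelwise) lower bound of
the input projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .image_io import ImageStack, PixelGeometry, PlaneImage
from .particle_analysis import (
    BinaryMask,
    Particle,
    ParticleCriterion,
    binarize,
    label_particles,
    sd_threshold,
    subtract_mask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CleanSettings",
    "RemovalRecord",
    "remove_large_particles",
    "remove_large_particles_stack",
    "subtract_autofluorescence",
    "max_intensity_projection",
    "remove_small_particles",
    "clean_images",
]

#: Default size/circularity removal ladder: (min area µm², min circularity).
#: Low-circularity gates demand large areas so elongated fibers survive.
DEFAULT_CRITERIA = (
    (40.0, 0.17),
    (25.0, 0.32),
    (15.0, 0.40),
    (10.0, 0.70),
    (5.0, 0.80),
)

#: Threshold multipliers for the four large-particle removal iterations.
DEFAULT_ITERATION_KS = (1.5, 2.0, 2.5, 3.0)


@dataclass
class CleanSettings:
    """Full parameterization of the three removal stages.

    Parameters
    ----------
    criteria
        1–5 size/circularity gates for large-particle removal, OR-combined.
    iteration_ks
        Strictly increasing SD multipliers; one removal pass per value, each
        thresholding the image as it stands after the previous pass.
    af_k
        SD multiplier for binarizing the autofluorescence channel (default 1;
        raise it if brightly labeled fibers bleed faintly into that channel).
    small_max_area_um2, small_circ_range, small_k
        Small-particle stage: on the MIP thresholded at ``mean + small_k·SD``,
        particles with area ≤ ``small_max_area_um2`` and circularity inside
        the closed ``small_circ_range`` are removed.
    use_af_subtraction
        Disable to run the morphology-only pipeline when no autofluorescence
        channel was acquired.
    """

    criteria: list[ParticleCriterion] = field(
        default_factory=lambda: [ParticleCriterion(a, c) for a, c in DEFAULT_CRITERIA]
    )
    iteration_ks: list[float] = field(default_factory=lambda: list(DEFAULT_ITERATION_KS))
    af_k: float = 1.0
    small_max_area_um2: float = 1.0
    small_circ_range: tuple[float, float] = (0.99, 1.0)
    small_k: float = 1.0
    use_af_subtraction: bool = True

    def __post_init__(self) -> None:
        self.criteria = [
            c if isinstance(c, ParticleCriterion) else ParticleCriterion(*c)
            for c in self.criteria
        ]
        if not 1 <= len(self.criteria) <= 5:
            raise ValueError(
                f"between 1 and 5 removal criteria required, got {len(self.criteria)}"
            )
        ks = list(self.iteration_ks)
        if not ks or any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("iteration_ks must be non-empty and strictly increasing")
        self.iteration_ks = [float(k) for k in ks]
        lo, hi = self.small_circ_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("small_circ_range must be an interval within [0, 1]")
        self.small_circ_range = (float(lo), float(hi))
        if self.af_k < 0 or self.small_k < 0:
            raise ValueError("threshold multipliers must be non-negative")

    # -- config round-trip --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "criteria": [[c.min_area_um2, c.min_circularity] for c in self.criteria],
            "iteration_ks": list(self.iteration_ks),
            "af_k": self.af_k,
            "small_max_area_um2": self.small_max_area_um2,
            "small_circ_range": list(self.small_circ_range),
            "small_k": self.small_k,
            "use_af_subtraction": self.use_af_subtraction,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CleanSettings":
        known = {
            "criteria",
            "iteration_ks",
            "af_k",
            "small_max_area_um2",
            "small_circ_range",
            "small_k",
            "use_af_subtraction",
        }
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown settings keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "criteria" in kwargs:
            kwargs["criteria"] = [ParticleCriterion(*pair) for pair in kwargs["criteria"]]
        if "small_circ_range" in kwargs:
            kwargs["small_circ_range"] = tuple(kwargs["small_circ_range"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "CleanSettings":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RemovalRecord:
    """One particle removed at some stage, for auditing and optimization.

    ``stage`` is ``"large"`` or ``"small"``; ``k`` the SD multiplier of the
    iteration that removed it; ``channel``/``z`` locate the plane (``z`` is
    None for the MIP stage).
    """

    particle: Particle
    stage: str
    k: float
    channel: int
    z: int | None


def _remove_matching(
    pixels: np.ndarray,
    geometry: PixelGeometry,
    k: float,
    selector,
) -> tuple[np.ndarray, list[Particle]]:
    """Threshold at mean+k·SD, remove particles picked by ``selector``."""
    thr = sd_threshold(pixels, k)
    mask = binarize(pixels, thr, geometry)
    particles = label_particles(mask)
    doomed = [p for p in particles if selector(p)]
    if not doomed:
        return pixels, []
    removal = np.zeros_like(mask.on_pixels)
    for p in doomed:
        removal[p.coords[:, 0], p.coords[:, 1]] = True
    out = subtract_mask(pixels, BinaryMask(removal, geometry))
    return out, doomed


def remove_large_particles(
    plane: PlaneImage,
    criteria: Sequence[ParticleCriterion] | None = None,
    iteration_ks: Sequence[float] | None = None,
    *,
    records: list[RemovalRecord] | None = None,
    channel: int = 0,
    z: int | None = None,
) -> PlaneImage:
    """Morphology-based artifact removal on one plane.

    For each SD multiplier in ``iteration_ks`` (in order): re-threshold the
    current image at ``mean + k·SD``, measure the particles, and zero every
    particle that meets any (min-area, min-circularity) gate.  Statistics are
    recomputed per iteration because each subtraction lowers the mean and SD,
    letting later, higher-``k`` passes reach structures that were initially
    below threshold relative to bright artifacts.
    """
    if criteria is None:
        criteria = [ParticleCriterion(a, c) for a, c in DEFAULT_CRITERIA]
    criteria = list(criteria)
    if not criteria:
        raise ValueError("at least one removal criterion is required")
    if iteration_ks is None:
        iteration_ks = DEFAULT_ITERATION_KS
    pixels = plane.pixels
    for k in iteration_ks:
        pixels, doomed = _remove_matching(
            pixels,
            plane.geometry,
            k,
            lambda p: any(c.matches(p) for c in criteria),
        )
        if records is not None:
            records.extend(
                RemovalRecord(particle=p, stage="large", k=k, channel=channel, z=z)
                for p in doomed
            )
    return PlaneImage(pixels, plane.bit_depth, plane.geometry, name=plane.name)


def remove_large_particles_stack(
    stack: ImageStack,
    criteria: Sequence[ParticleCriterion] | None = None,
    iteration_ks: Sequence[float] | None = None,
    *,
    records: list[RemovalRecord] | None = None,
) -> ImageStack:
    """Apply large-particle removal to every (channel, z) plane.

    The autofluorescence channel, when assigned, passes through unmodified:
    it is a background reference and must stay intact until the subtraction
    step.  Threshold statistics are per plane, which tolerates
    depth-dependent brightness falloff through the section.
    """
    out = stack.copy()
    for c in range(stack.n_channels):
        if c == stack.af_channel:
            continue
        for z in range(stack.n_z):
            plane = PlaneImage(stack.voxels[c, z], stack.bit_depth, stack.geometry)
            cleaned = remove_large_particles(
                plane, criteria, iteration_ks, records=records, channel=c, z=z
            )
            out.voxels[c, z] = cleaned.pixels
    return out


def subtract_autofluorescence(stack: ImageStack, af_k: float = 1.0) -> ImageStack:
    """Zero, in every signal channel, the pixels bright in the AF channel.

    Each z-slice of the autofluorescence channel is binarized at
    ``mean + af_k·SD`` (slice statistics) and the resulting mask is
    subtracted from the same slice of every other channel.  The AF channel
    itself is left untouched in the returned stack for provenance; it is
    dropped only when final MIPs are produced.
    """
    if stack.af_channel is None:
        raise ValueError(
            "no autofluorescence channel assigned: set ImageStack.af_channel, "
            "or disable autofluorescence subtraction "
            "(CleanSettings.use_af_subtraction=False) to run the "
            "morphology-only pipeline"
        )
    out = stack.copy()
    af = stack.af_channel
    for z in range(stack.n_z):
        af_slice = stack.voxels[af, z]
        thr = sd_threshold(af_slice, af_k)
        mask = binarize(af_slice, thr, stack.geometry)
        for c in range(stack.n_channels):
            if c == af:
                continue
            out.voxels[c, z] = subtract_mask(out.voxels[c, z], mask)
    return out


def max_intensity_projection(stack: ImageStack, channel: int) -> PlaneImage:
    """Exact per-pixel maximum over z of one channel."""
    if not 0 <= channel < stack.n_channels:
        raise IndexError(f"channel {channel} out of range")
    mip = stack.voxels[channel].max(axis=0)
    name = (
        stack.channel_names[channel] if stack.channel_names else f"C{channel}"
    )
    return PlaneImage(mip, stack.bit_depth, stack.geometry, name=name)


def remove_small_particles(
    mip: PlaneImage,
    small_max_area_um2: float = 1.0,
    small_circ_range: tuple[float, float] = (0.99, 1.0),
    small_k: float = 1.0,
    *,
    records: list[RemovalRecord] | None = None,
    channel: int = 0,
) -> PlaneImage:
    """Remove speckle too small and too round to be an axon from a MIP.

    One pass: threshold at ``mean + small_k·SD``; particles with area at most
    ``small_max_area_um2`` µm² and circularity inside the closed
    ``small_circ_range`` are zeroed.
    """
    lo, hi = small_circ_range
    pixels, doomed = _remove_matching(
        mip.pixels,
        mip.geometry,
        small_k,
        lambda p: p.area_um2 <= small_max_area_um2 and lo <= p.circularity <= hi,
    )
    if records is not None:
        records.extend(
            RemovalRecord(particle=p, stage="small", k=small_k, channel=channel, z=None)
            for p in doomed
        )
    return PlaneImage(pixels, mip.bit_depth, mip.geometry, name=mip.name)


def clean_images(
    stack: ImageStack,
    settings: CleanSettings | None = None,
    *,
    records: list[RemovalRecord] | None = None,
) -> list[PlaneImage]:
    """Run the full cleaning pipeline; one cleaned MIP per signal channel.

    Stages: large-particle removal on every z-slice → autofluorescence
    subtraction (optional) → per-channel maximum intensity projection →
    small-particle removal on each MIP.  The autofluorescence channel is
    excluded from the outputs.
    """
    if settings is None:
        settings = CleanSettings()
    if settings.use_af_subtraction and stack.af_channel is None:
        raise ValueError(
            "autofluorescence subtraction requested but the stack has no "
            "af_channel; assign one or set use_af_subtraction=False"
        )
    _warn_near_blank_slices(stack)
    working = remove_large_particles_stack(
        stack, settings.criteria, settings.iteration_ks, records=records
    )
    if settings.use_af_subtraction:
        working = subtract_autofluorescence(working, settings.af_k)
    outputs: list[PlaneImage] = []
    for c in range(stack.n_channels):
        if c == stack.af_channel:
            continue
        mip = max_intensity_projection(working, c)
        cleaned = remove_small_particles(
            mip,
            settings.small_max_area_um2,
            settings.small_circ_range,
            settings.small_k,
            records=records,
            channel=c,
        )
        outputs.append(cleaned)
    return outputs


def _warn_near_blank_slices(stack: ImageStack, fraction: float = 0.02) -> None:
    """Log slices whose nonzero fraction is tiny; they should be cropped.

    Empty slices above or below the tissue distort per-slice threshold
    statistics in principle; with the strict ``>`` comparison a perfectly
    constant slice is a harmless no-op, but near-blank ones are still best
    removed with :func:`pydefine.image_io.crop_z`.
    """
    for z in range(stack.n_z):
        frac = float(np.count_nonzero(stack.voxels[:, z]) / stack.voxels[:, z].size)
        if frac < fraction:
            logger.warning(
                "z-slice %d is %.1f%% nonzero; consider cropping blank slices "
                "before cleaning",
                z,
                100 * frac,
            )
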