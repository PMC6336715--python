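"""Non-interactive settings recommendation from user markings.

The cleaning stage is parameterized by a ladder of (area, circularity) gates
plus an autofluorescence threshold.  Tuning these on a new tissue or
fluorophore is usually done by inspecting one representative image:
:func:`preview_processing` runs the full pipeline on it and returns every
particle that was removed, and :func:`recommend_settings` turns markings of
mistakes ("this removed particle was a fiber", "this surviving blob is an
artifact") into a minimally-adjusted settings object.

The adjustment heuristic is this package's own design (the underlying
macro's heuristic is unpublished): each mistake is fixed by the smallest
relative change to a single gate, with a 1 % margin, falling back to a lower
autofluorescence threshold for artifacts that morphology cannot separate.
It is deliberately isolated in this module so it can be swapped out.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .artifact_removal import (
    CleanSettings,
    RemovalRecord,
    clean_images,
    max_intensity_projection,
)
from .image_io import ImageStack, PlaneImage
from .particle_analysis import (
    Particle,
    ParticleCriterion,
    binarize,
    label_particles,
    sd_threshold,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Marking",
    "preview_processing",
    "recommend_settings",
    "read_markings",
]

MARGIN = 0.01  # tighten/loosen past the offending particle by 1 % of its value
MIN_AF_K = 0.5


@dataclass(frozen=True)
class Marking:
    """A user-marked mistake, as a seed point inside the object.

    ``kind`` is ``"wrongly_removed_fiber"`` (a removed particle that was a
    real axon) or ``"wrongly_kept_artifact"`` (a surviving structure that is
    noise).
    """

    kind: str
    y: int
    x: int

    def __post_init__(self) -> None:
        if self.kind not in ("wrongly_removed_fiber", "wrongly_kept_artifact"):
            raise ValueError(f"unknown marking kind {self.kind!r}")


def preview_processing(
    stack: ImageStack, settings: CleanSettings | None = None
) -> tuple[PlaneImage, PlaneImage, list[RemovalRecord]]:
    """Clean one representative stack, reporting what was removed.

    Returns the first signal channel's MIP before processing, the cleaned MIP
    after, and the full list of removal records (particle, stage, threshold
    multiplier, plane) across all stages and channels.
    """
    settings = settings or CleanSettings()
    first_signal = next(
        c for c in range(stack.n_channels) if c != stack.af_channel
    )
    before = max_intensity_projection(stack, first_signal)
    records: list[RemovalRecord] = []
    outputs = clean_images(stack, settings, records=records)
    return before, outputs[0], records


def _tighten(
    criteria: list[ParticleCriterion], particle: Particle
) -> list[ParticleCriterion]:
    """Raise every gate the particle matches until it matches none.

    For each matched gate, either the minimum area is raised just above the
    particle's area or the minimum circularity just above its circularity —
    whichever is the smaller relative change to that gate.  When the
    circularity route would exceed 1 the area route is used.
    """
    out = []
    for c in criteria:
        if not c.matches(particle):
            out.append(c)
            continue
        new_area = particle.area_um2 * (1 + MARGIN)
        new_circ = particle.circularity * (1 + MARGIN)
        rel_area = (new_area - c.min_area_um2) / c.min_area_um2
        rel_circ = (
            (new_circ - c.min_circularity) / c.min_circularity
            if c.min_circularity > 0
            else np.inf
        )
        if new_circ <= 1.0 and rel_circ <= rel_area:
            out.append(ParticleCriterion(c.min_area_um2, new_circ))
        else:
            out.append(ParticleCriterion(new_area, c.min_circularity))
    return out


def _loosen(
    criteria: list[ParticleCriterion], particle: Particle
) -> list[ParticleCriterion] | None:
    """Lower the single gate needing the smallest relative change to catch
    the particle; None when no gate can be loosened meaningfully."""
    best: tuple[float, int, ParticleCriterion] | None = None
    for i, c in enumerate(criteria):
        new_area = min(c.min_area_um2, particle.area_um2 * (1 - MARGIN))
        new_circ = min(c.min_circularity, particle.circularity * (1 - MARGIN))
        if new_area <= 0:
            continue
        cost = (c.min_area_um2 - new_area) / c.min_area_um2
        if c.min_circularity > 0:
            cost += (c.min_circularity - new_circ) / c.min_circularity
        cand = ParticleCriterion(new_area, max(0.0, new_circ))
        if best is None or cost < best[0]:
            best = (cost, i, cand)
    if best is None:
        return None
    _, i, cand = best
    out = list(criteria)
    out[i] = cand
    return out


def _find_removed(
    removed: list[RemovalRecord], y: int, x: int
) -> RemovalRecord | None:
    for rec in removed:
        if (y, x) in rec.particle.pixel_set:
            return rec
    return None


def _af_visibility(af_stack: np.ndarray, footprint: np.ndarray) -> float:
    """Largest k such that some footprint pixel clears mean + k·SD of its
    autofluorescence slice; -inf when the AF signal is flat."""
    best = -np.inf
    for z in range(af_stack.shape[0]):
        sl = af_stack[z]
        sd = float(sl.std())
        if sd == 0:
            continue
        peak = float(sl[footprint].max())
        best = max(best, (peak - float(sl.mean())) / sd)
    return best


def recommend_settings(
    current: CleanSettings,
    removed_particles: list[RemovalRecord],
    markings: list[Marking],
    after: PlaneImage | None = None,
    af_stack: np.ndarray | None = None,
) -> CleanSettings:
    """Derive revised settings from marked processing mistakes.

    ``after`` (the cleaned MIP from :func:`preview_processing`) is needed to
    measure wrongly kept artifacts; ``af_stack`` is the autofluorescence
    channel's ``(z, y, x)`` voxels, used to decide whether a lower
    autofluorescence threshold would catch an artifact that morphology
    cannot.  Markings that hit no particle are logged and ignored.
    """
    if not markings:
        raise ValueError("at least one marking is required")
    criteria = list(current.criteria)
    af_k = current.af_k
    small_max = current.small_max_area_um2

    after_particles: list[Particle] | None = None
    if after is not None:
        low_k = min(current.iteration_ks)
        thr = sd_threshold(after.pixels, low_k)
        after_particles = label_particles(
            binarize(after.pixels, thr, after.geometry)
        )

    for m in markings:
        if m.kind == "wrongly_removed_fiber":
            rec = _find_removed(removed_particles, m.y, m.x)
            if rec is None:
                logger.warning(
                    "marking at (%d, %d) hits no removed particle; ignored",
                    m.y,
                    m.x,
                )
                continue
            if rec.stage == "small":
                # protect it by excluding its size from the small-particle gate
                small_max = min(small_max, rec.particle.area_um2 * (1 - MARGIN))
                continue
            criteria = _tighten(criteria, rec.particle)
        else:  # wrongly_kept_artifact
            if after_particles is None:
                logger.warning(
                    "artifact marking at (%d, %d) needs the processed image; "
                    "ignored",
                    m.y,
                    m.x,
                )
                continue
            hit = next(
                (p for p in after_particles if (m.y, m.x) in p.pixel_set), None
            )
            if hit is None:
                logger.warning(
                    "marking at (%d, %d) hits no particle in the processed "
                    "image; ignored",
                    m.y,
                    m.x,
                )
                continue
            if not any(c.matches(hit) for c in criteria):
                loosened = _loosen(criteria, hit)
                if loosened is not None:
                    criteria = loosened
                    continue
            # Morphology already selects (or cannot select) this particle;
            # fall back to the autofluorescence route.
            footprint = np.zeros(after.pixels.shape, dtype=bool)
            footprint[hit.coords[:, 0], hit.coords[:, 1]] = True
            k_vis = (
                _af_visibility(af_stack, footprint)
                if af_stack is not None
                else -np.inf
            )
            if k_vis > MIN_AF_K and k_vis * (1 - MARGIN) < af_k:
                af_k = max(MIN_AF_K, k_vis * (1 - MARGIN))
            else:
                logger.warning(
                    "artifact at (%d, %d) (area %.2f µm², circularity %.3f) "
                    "is not separable by current features",
                    m.y,
                    m.x,
                    hit.area_um2,
                    hit.circularity,
                )

    return replace(
        current,
        criteria=criteria,
        af_k=af_k,
        small_max_area_um2=small_max,
    )


def read_markings(path: str | Path) -> list[Marking]:
    """Read markings from a CSV with columns ``kind,y,x`` (header optional)."""
    out: list[Marking] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip() or row[0].strip() == "kind":
                continue
            out.append(Marking(row[0].strip(), int(row[1]), int(row[2])))
    return out
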