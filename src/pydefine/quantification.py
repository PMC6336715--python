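"""Fiber quantification: background-calibrated thresholding of a MIP.

The user (or an automatic proposer) supplies ten small axon-free background
regions, 12 × 12 µm each.  The mean and SD of the pooled background pixels
set an image-specific threshold at ``mean + 4·SD``; the fiber estimate is the
image area (µm²) above that threshold.  Calibrating the threshold per image
absorbs the background-intensity differences between brain regions, animals
and staining batches that defeat a single global cutoff.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np

from .image_io import PixelGeometry, PlaneImage, read_plane, write_outputs
from .particle_analysis import BinaryMask, binarize

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundRegion",
    "QuantifyResult",
    "background_stats",
    "quantify_fibers",
    "quantify_batch",
    "propose_regions",
    "read_region_sidecar",
    "write_region_sidecar",
]

DEFAULT_REGION_SIDE_UM = 12.0
DEFAULT_REGION_COUNT = 10
DEFAULT_K = 4.0


@dataclass(frozen=True)
class BackgroundRegion:
    """A square background patch: top-left pixel plus physical side length.

    The pixel extent per axis is ``round(side_um / µm-per-px)``, at least one
    pixel, so the same physical 12 µm patch adapts to the acquisition's
    sampling (e.g. ~14 px at 0.830 µm/px, ~58 px at 0.208 µm/px).
    """

    y0: int
    x0: int
    side_um: float = DEFAULT_REGION_SIDE_UM

    def extent(self, geometry: PixelGeometry) -> tuple[int, int]:
        """(height, width) in pixels under the given geometry."""
        h = max(1, round(self.side_um / geometry.y_um_per_px))
        w = max(1, round(self.side_um / geometry.x_um_per_px))
        return h, w

    def slices(self, geometry: PixelGeometry) -> tuple[slice, slice]:
        h, w = self.extent(geometry)
        return slice(self.y0, self.y0 + h), slice(self.x0, self.x0 + w)


def _region_mask(
    mip: PlaneImage, regions: list[BackgroundRegion]
) -> np.ndarray:
    """Boolean mask of all region pixels; errors on out-of-bounds regions."""
    H, W = mip.pixels.shape
    mask = np.zeros((H, W), dtype=bool)
    overlap = False
    for i, r in enumerate(regions):
        h, w = r.extent(mip.geometry)
        if r.y0 < 0 or r.x0 < 0 or r.y0 + h > H or r.x0 + w > W:
            raise ValueError(
                f"background region {i} at (y0={r.y0}, x0={r.x0}) with extent "
                f"{h}×{w} px lies outside the {H}×{W} image"
            )
        sy, sx = r.slices(mip.geometry)
        if mask[sy, sx].any():
            overlap = True
        mask[sy, sx] = True
    if overlap:
        logger.warning(
            "background regions overlap; shared pixels are counted once"
        )
    return mask


def background_stats(
    mip: PlaneImage, regions: list[BackgroundRegion]
) -> tuple[float, float]:
    """Pooled mean and population SD of all background-region pixels.

    All region pixels are pooled into one multiset (overlaps counted once,
    with a warning) rather than averaging per-region statistics: the pooled
    estimator is what a single combined background sample would give and is
    better conditioned when individual regions are small.
    """
    if not regions:
        raise ValueError("at least one background region is required")
    mask = _region_mask(mip, regions)
    vals = mip.pixels[mask]
    return float(vals.mean()), float(vals.std())


@dataclass
class QuantifyResult:
    """Per-image quantification output."""

    background_mean: float
    background_sd: float
    threshold: float
    fiber_area_um2: float
    fiber_mask: BinaryMask
    source_image: str = ""


def quantify_fibers(
    mip: PlaneImage,
    regions: list[BackgroundRegion],
    k: float = DEFAULT_K,
) -> QuantifyResult:
    """Threshold a MIP at ``background mean + k·SD`` and report fiber area.

    Pixels strictly above the threshold are counted as fiber; the area is
    their count times the pixel area in µm².  With the default ``k = 4`` and
    roughly Gaussian background, a negligible fraction of true background
    clears the cutoff, so the measurement tracks the labeled structures.
    """
    mean, sd = background_stats(mip, regions)
    threshold = mean + k * sd
    mask = binarize(mip.pixels, threshold, mip.geometry)
    return QuantifyResult(
        background_mean=mean,
        background_sd=sd,
        threshold=threshold,
        fiber_area_um2=mask.area_um2,
        fiber_mask=mask,
        source_image=mip.name,
    )


def propose_regions(
    mip: PlaneImage,
    n: int = DEFAULT_REGION_COUNT,
    side_um: float = DEFAULT_REGION_SIDE_UM,
) -> list[BackgroundRegion]:
    """Automatic background-region proposer (extension to the manual flow).

    Tiles the image into non-overlapping ``side_um`` squares and returns the
    ``n`` tiles with the lowest mean intensity — a stand-in for the user's
    choice of axon-free patches when running headless.  Inspect the proposals
    on real data; a dim artifact-free tile is not guaranteed to be axon-free.
    """
    probe = BackgroundRegion(0, 0, side_um)
    h, w = probe.extent(mip.geometry)
    H, W = mip.pixels.shape
    tiles: list[tuple[float, BackgroundRegion]] = []
    for y0 in range(0, H - h + 1, h):
        for x0 in range(0, W - w + 1, w):
            m = float(mip.pixels[y0 : y0 + h, x0 : x0 + w].mean())
            tiles.append((m, BackgroundRegion(y0, x0, side_um)))
    if len(tiles) < n:
        raise ValueError(
            f"image too small: only {len(tiles)} disjoint {side_um} µm tiles "
            f"fit, {n} regions requested"
        )
    tiles.sort(key=lambda t: (t[0], t[1].y0, t[1].x0))
    return [r for _, r in tiles[:n]]


# ---------------------------------------------------------------------------
# Region sidecars and batch quantification


def read_region_sidecar(
    path: str | Path,
    side_um: float = DEFAULT_REGION_SIDE_UM,
    geometry: PixelGeometry | None = None,
) -> list[BackgroundRegion]:
    """Read background regions from a CSV sidecar.

    Columns ``y0,x0`` (header optional), coordinates in pixels; with a
    ``unit`` column equal to ``um`` the coordinates are physical and require
    ``geometry`` to convert.
    """
    regions: list[BackgroundRegion] = []
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and row[0].strip()]
    if rows and not rows[0][0].strip().lstrip("-").isdigit():
        rows = rows[1:]  # header
    for row in rows:
        y, x = float(row[0]), float(row[1])
        unit = row[2].strip().lower() if len(row) > 2 and row[2].strip() else "px"
        if unit == "um":
            if geometry is None:
                raise ValueError(f"{path}: µm coordinates need a pixel geometry")
            y /= geometry.y_um_per_px
            x /= geometry.x_um_per_px
        elif unit != "px":
            raise ValueError(f"{path}: unknown coordinate unit {unit!r}")
        regions.append(BackgroundRegion(int(round(y)), int(round(x)), side_um))
    return regions


def write_region_sidecar(path: str | Path, regions: list[BackgroundRegion]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["y0", "x0"])
        for r in regions:
            writer.writerow([r.y0, r.x0])


REPORT_COLUMNS = (
    "image",
    "background_mean",
    "background_sd",
    "threshold",
    "fiber_area_um2",
    "status",
)


def quantify_batch(
    folder: str | Path,
    regions_per_image: dict[str, list[BackgroundRegion]],
    k: float = DEFAULT_K,
    out_root: str | Path | None = None,
    run_date: date | None = None,
    geometry_override: PixelGeometry | None = None,
) -> tuple[Path, list[Path], list[QuantifyResult]]:
    """Quantify every single-channel MIP in ``folder``.

    ``regions_per_image`` maps image stems to their background regions; an
    image without regions is skipped with a warning and flagged in the
    report.  Writes a tab-delimited report plus one binary fiber mask per
    image into the dated ``DEFiNE_Quantified_Fibers_`` folder.  Returns
    (report path, mask paths, results).
    """
    folder = Path(folder)
    out_root = Path(out_root) if out_root is not None else folder
    run_date = run_date or date.today()
    paths = sorted(
        p for p in folder.iterdir() if p.suffix.lower() in {".tif", ".tiff"}
    )
    results: list[QuantifyResult] = []
    mask_planes: list[PlaneImage] = []
    rows: list[tuple] = []
    for p in paths:
        stem = p.stem
        if stem not in regions_per_image:
            logger.warning("no background regions for %s; skipped", p.name)
            rows.append((stem, "", "", "", "", "no_regions"))
            continue
        mip = read_plane(p, geometry_override=geometry_override)
        res = quantify_fibers(mip, regions_per_image[stem], k=k)
        res.source_image = stem
        results.append(res)
        rows.append(
            (
                stem,
                f"{res.background_mean:.6f}",
                f"{res.background_sd:.6f}",
                f"{res.threshold:.6f}",
                f"{res.fiber_area_um2:.6f}",
                "ok",
            )
        )
        mask_planes.append(
            PlaneImage(
                res.fiber_mask.on_pixels.astype(np.uint8) * 255,
                bit_depth=8,
                geometry=mip.geometry,
                name=f"{stem}_fiber_mask",
            )
        )
    mask_paths = write_outputs(mask_planes, run_date, "quantified", out_root)
    report_dir = mask_paths[0].parent if mask_paths else out_root
    report_path = Path(report_dir) / "quantified_fibers.txt"
    with open(report_path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return report_path, mask_paths, results
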