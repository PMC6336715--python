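"""Reading and writing of multi-channel z-stacks with physical pixel sizes.

All images in the pipeline carry a :class:`PixelGeometry` so that particle
areas and perimeters can be reported in micrometres, the unit every removal
criterion is expressed in.  Stacks are normalised to a fixed in-memory axis
order ``(channel, z, y, x)`` with the origin at the top-left corner,
regardless of how the planes were interleaved on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "PixelGeometry",
    "ImageStack",
    "PlaneImage",
    "read_stack",
    "write_stack",
    "read_plane",
    "write_plane",
    "crop_z",
    "write_outputs",
]


@dataclass(frozen=True)
class PixelGeometry:
    """Physical size of one pixel, in micrometres per pixel, per axis.

    Confocal acquisitions are frequently anisotropic in z but may also use
    non-square xy sampling, so x and y are kept separate.
    """

    x_um_per_px: float
    y_um_per_px: float

    def __post_init__(self) -> None:
        if not (self.x_um_per_px > 0 and self.y_um_per_px > 0):
            raise ValueError(
                f"pixel sizes must be strictly positive, got "
                f"({self.x_um_per_px}, {self.y_um_per_px})"
            )

    @property
    def pixel_area_um2(self) -> float:
        """Area of a single pixel in square micrometres."""
        return self.x_um_per_px * self.y_um_per_px


_ALLOWED_DEPTHS = (8, 16)


def _check_intensities(arr: np.ndarray, bit_depth: int) -> None:
    if bit_depth not in _ALLOWED_DEPTHS:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(
            f"pixel data must be integer-typed, got {arr.dtype}; convert the "
            "image to 8- or 16-bit integers before processing"
        )
    if arr.size and (arr.min() < 0 or arr.max() > 2**bit_depth - 1):
        raise ValueError(
            f"intensities outside [0, {2 ** bit_depth - 1}] for bit depth {bit_depth}"
        )


@dataclass
class ImageStack:
    """A multi-channel z-stack: integer voxels indexed ``(channel, z, y, x)``.

    ``af_channel`` names the autofluorescence channel — the acquisition
    channel that samples background fluorescence but not labeled axons — when
    one was collected.
    """

    voxels: np.ndarray
    bit_depth: int
    geometry: PixelGeometry
    channel_names: list[str] = field(default_factory=list)
    af_channel: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4-D (channel, z, y, x), got shape {self.voxels.shape}"
            )
        _check_intensities(self.voxels, self.bit_depth)
        if not self.channel_names:
            self.channel_names = [f"C{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")
        if self.af_channel is not None and not (
            0 <= self.af_channel < self.n_channels
        ):
            raise ValueError(
                f"af_channel {self.af_channel} out of range for "
                f"{self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel(self, index: int) -> np.ndarray:
        """The ``(z, y, x)`` sub-array of one channel."""
        return self.voxels[index]

    def copy(self) -> "ImageStack":
        return ImageStack(
            voxels=self.voxels.copy(),
            bit_depth=self.bit_depth,
            geometry=self.geometry,
            channel_names=list(self.channel_names),
            af_channel=self.af_channel,
        )


@dataclass
class PlaneImage:
    """A single-channel 2-D image, e.g. a maximum intensity projection."""

    pixels: np.ndarray
    bit_depth: int
    geometry: PixelGeometry
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        _check_intensities(self.pixels, self.bit_depth)

    def copy(self) -> "PlaneImage":
        return replace(self, pixels=self.pixels.copy())


# ---------------------------------------------------------------------------
# TIFF I/O


def _dtype_for(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8 if bit_depth == 8 else np.uint16)


def _bit_depth_for(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise TypeError(
        f"unsupported pixel dtype {dtype}; convert the image to 8- or 16-bit "
        "unsigned integers before processing"
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF, recording pixel sizes and channel names."""
    path = Path(path)
    data = stack.voxels.astype(_dtype_for(stack.bit_depth), copy=False)
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeX": stack.geometry.x_um_per_px,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.geometry.y_um_per_px,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",  # never misread small X-extents as RGBA
        metadata=metadata,
        resolution=(1e4 / stack.geometry.x_um_per_px, 1e4 / stack.geometry.y_um_per_px),
        resolutionunit="CENTIMETER",
    )
    return path


def _geometry_from_ome(tif: tifffile.TiffFile) -> PixelGeometry | None:
    try:
        ome = tif.ome_metadata
    except Exception:
        return None
    if not ome:
        return None
    mx = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', ome)
    my = re.search(r'PhysicalSizeY="([\d.eE+-]+)"', ome)
    if mx and my:
        return PixelGeometry(float(mx.group(1)), float(my.group(1)))
    return None


def _geometry_from_tags(tif: tifffile.TiffFile) -> PixelGeometry | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "YResolution" not in tags:
        return None
    xres = tags["XResolution"].value
    yres = tags["YResolution"].value
    unit = tags.get("ResolutionUnit")
    unit_val = getattr(unit, "value", None) if unit is not None else None
    # px per unit -> µm per px
    if hasattr(unit_val, "value"):
        unit_val = unit_val.value
    scale = {2: 25400.0, 3: 10000.0}.get(unit_val)  # inch, centimetre
    if scale is None:
        return None

    def to_um(res: object) -> float | None:
        if isinstance(res, tuple):
            num, den = res
            if num == 0:
                return None
            return scale * den / num
        res = float(res)
        return scale / res if res else None

    x = to_um(xres)
    y = to_um(yres)
    if x is None or y is None:
        return None
    return PixelGeometry(x, y)


def _channel_names_from_ome(tif: tifffile.TiffFile, n: int) -> list[str] | None:
    try:
        ome = tif.ome_metadata
    except Exception:
        return None
    if not ome:
        return None
    names = re.findall(r'<Channel[^>]*\bName="([^"]*)"', ome)
    if len(names) == n:
        return list(names)
    return None


def read_stack(
    path: str | Path,
    geometry_override: PixelGeometry | None = None,
    af_channel: int | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into the canonical ``(channel, z, y, x)`` layout.

    Pixel-size precedence: explicit ``geometry_override``, then OME
    ``PhysicalSize`` attributes, then TIFF resolution tags.  A file carrying
    none of these raises, naming the file, because every downstream criterion
    is specified in µm².
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "CZYX", "ZCYX", "YX", "ZYX"
        geometry = (
            geometry_override
            or _geometry_from_ome(tif)
            or _geometry_from_tags(tif)
        )
        if geometry is None:
            raise ValueError(
                f"{path}: no pixel-size metadata (OME PhysicalSize or TIFF "
                "resolution tags) and no geometry override supplied"
            )
        if not np.issubdtype(data.dtype, np.integer):
            raise TypeError(
                f"{path}: pixel data is {data.dtype}; convert the image to "
                "8- or 16-bit integers before processing"
            )
        # Normalise axes to CZYX, inserting length-1 axes as needed.
        axes = axes.replace("S", "C").replace("I", "Z").replace("Q", "Z")
        for ax in axes:
            if ax not in "CZYX":
                raise ValueError(f"{path}: unsupported axis {ax!r} in layout {axes}")
        for ax in "CZ":
            if ax not in axes:
                data = np.expand_dims(data, 0)
                axes = ax + axes
        order = [axes.index(ax) for ax in "CZYX"]
        data = np.transpose(data, order)
        bit_depth = _bit_depth_for(data.dtype)
        names = _channel_names_from_ome(tif, data.shape[0])
    return ImageStack(
        voxels=data,
        bit_depth=bit_depth,
        geometry=geometry,
        channel_names=names or [],
        af_channel=af_channel,
    )


def write_plane(plane: PlaneImage, path: str | Path) -> Path:
    """Write a single-plane TIFF with resolution tags carrying pixel size."""
    path = Path(path)
    tifffile.imwrite(
        path,
        plane.pixels.astype(_dtype_for(plane.bit_depth), copy=False),
        photometric="minisblack",
        resolution=(1e4 / plane.geometry.x_um_per_px, 1e4 / plane.geometry.y_um_per_px),
        resolutionunit="CENTIMETER",
    )
    return path


def read_plane(
    path: str | Path, geometry_override: PixelGeometry | None = None
) -> PlaneImage:
    """Read a single-channel, single-plane image (e.g. a MIP)."""
    stack = read_stack(path, geometry_override=geometry_override)
    if stack.n_channels != 1 or stack.n_z != 1:
        raise ValueError(
            f"{path}: expected a single-channel single-plane image, got "
            f"{stack.n_channels} channel(s) × {stack.n_z} slice(s)"
        )
    return PlaneImage(
        pixels=stack.voxels[0, 0],
        bit_depth=stack.bit_depth,
        geometry=stack.geometry,
        name=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Stack helpers and output-folder conventions


def crop_z(stack: ImageStack, z_first: int, z_last: int) -> ImageStack:
    """Keep z-slices ``z_first..z_last`` inclusive, all channels.

    Stacks should be cropped to drop slices imaged above or below the tissue
    before cleaning: slices that are (near-)empty carry dust and coverslip
    artifacts and degrade per-slice threshold statistics.
    """
    if not (0 <= z_first <= z_last < stack.n_z):
        raise IndexError(
            f"invalid z-crop [{z_first}, {z_last}] for stack with "
            f"{stack.n_z} slices"
        )
    return ImageStack(
        voxels=stack.voxels[:, z_first : z_last + 1].copy(),
        bit_depth=stack.bit_depth,
        geometry=stack.geometry,
        channel_names=list(stack.channel_names),
        af_channel=stack.af_channel,
    )


_KIND_PREFIX = {
    "processed": "DEFiNE_Processed_Images_",
    "quantified": "DEFiNE_Quantified_Fibers_",
}


def output_folder(out_root: str | Path, run_date: date, kind: str) -> Path:
    """Dated output folder path: ``DEFiNE_<Kind>_MM-DD-YYYY`` under out_root."""
    if kind not in _KIND_PREFIX:
        raise ValueError(f"kind must be one of {sorted(_KIND_PREFIX)}, got {kind!r}")
    stamp = f"{run_date.month:02d}-{run_date.day:02d}-{run_date.year:04d}"
    return Path(out_root) / f"{_KIND_PREFIX[kind]}{stamp}"


def write_outputs(
    images: Sequence[PlaneImage],
    run_date: date,
    kind: str,
    out_root: str | Path,
) -> list[Path]:
    """Save planes into the dated convention folder; returns paths in order.

    Each image is written as its own single-plane TIFF named after
    ``image.name`` (falling back to a positional name).
    """
    folder = output_folder(out_root, run_date, kind)
    folder.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for i, img in enumerate(images):
        stem = img.name or f"image_{i:03d}"
        p = folder / f"{stem}.tif"
        write_plane(img, p)
        paths.append(p)
    return paths
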