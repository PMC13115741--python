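"""Reading and writing of images, masks, annotations, traces and measurement tables.

Conventions used throughout the package
---------------------------------------
* Coordinates are 0-based ``(x, y) = (column, row)`` with pixel centers at
  integer coordinates.
* Images are 2D grayscale grids of non-negative floats in arbitrary
  fluorescence units.
* The physical pixel size is carried alongside the pixel grid rather than
  parsed from TIFF tags (tag dialects vary between microscope exporters).
  The default of 0.3 um/px corresponds to the 300 nm confocal sampling the
  morphometry defaults are calibrated for; when a reader falls back to it, a
  notice is logged.
* Annotations (scribbles and process traces) live in a single versioned JSON
  schema instead of ImageJ ``.roi`` binaries, so they diff and round-trip
  cleanly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 0.3
ANNOTATION_SCHEMA_VERSION = 1
ANNOTATION_LABELS = ("foreground", "background", "trace")


@dataclass(frozen=True)
class IntensityImage:
    """A 2D grayscale fluorescence image with a physical pixel size.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities (arbitrary units).
    pixel_size_um
        Physical edge length of one pixel in micrometers.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("intensity image must be 2D with at least 2x2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("intensity image contains non-finite values")
        if px.min() < 0:
            raise ValueError("intensity image contains negative values")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationMask:
    """A binary mask with the connectivity convention used for its objects."""

    pixels: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            raise ValueError("mask pixels must be boolean")
        if px.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class Polyline:
    """A labeled polyline: a scribble (foreground/background) or a trace."""

    label: str
    vertices: np.ndarray  # (n, 2) float array of (x, y) pixel coordinates
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("polyline needs at least 2 (x, y) vertices")
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {ANNOTATION_LABELS}"
            )
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class AnnotationSet:
    """Labeled polylines referencing one image (by its dimensions)."""

    width: int
    height: int
    items: tuple[Polyline, ...] = ()
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        object.__setattr__(self, "items", tuple(self.items))
        for i, item in enumerate(self.items):
            v = item.vertices
            if (
                v[:, 0].min() < 0
                or v[:, 1].min() < 0
                or v[:, 0].max() > self.width - 1
                or v[:, 1].max() > self.height - 1
            ):
                raise ValueError(
                    f"item {i} ({item.label!r}) has vertices outside the "
                    f"{self.width}x{self.height} image bounds"
                )

    def by_label(self, label: str) -> tuple[Polyline, ...]:
        return tuple(p for p in self.items if p.label == label)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def read_image(
    path: str | Path,
    channel: int | None = None,
    pixel_size_um: float | None = None,
) -> IntensityImage:
    """Read an 8/16-bit (or float) grayscale TIFF as an :class:`IntensityImage`.

    Multi-channel files require an explicit ``channel``; the channel axis is
    taken to be the smallest axis of the array. The pixel size is never read
    from TIFF tags: pass it explicitly or the 0.3 um default is used with a
    logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"ambiguous channel: image has shape {arr.shape}; pass channel="
            )
        axis = int(np.argmin(arr.shape))
        if not 0 <= channel < arr.shape[axis]:
            raise IndexError(
                f"channel {channel} out of range for {arr.shape[axis]} channels"
            )
        arr = np.take(arr, channel, axis=axis)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality: {arr.ndim}")
    if not (
        arr.dtype in (np.uint8, np.uint16) or np.issubdtype(arr.dtype, np.floating)
    ):
        raise ValueError(f"unsupported bit depth: {arr.dtype}")
    if pixel_size_um is None:
        pixel_size_um = DEFAULT_PIXEL_SIZE_UM
        logger.info(
            "no pixel size given for %s; defaulting to %.3g um/px", path, pixel_size_um
        )
    return IntensityImage(arr.astype(float), pixel_size_um)


def write_image(image: IntensityImage, path: str | Path) -> None:
    """Write an image as TIFF, as uint8/uint16 when lossless, else float32."""
    px = image.pixels
    if np.all(px == np.round(px)) and px.max() <= 65535:
        arr = px.astype(np.uint8 if px.max() <= 255 else np.uint16)
    else:
        arr = px.astype(np.float32)
    tifffile.imwrite(Path(path), arr)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit {0, 255} TIFF or PNG (by extension)."""
    arr = (mask.pixels.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        tifffile.imwrite(path, arr)


def read_mask(path: str | Path, connectivity: int = 8) -> SegmentationMask:
    """Read a binary mask image; any single nonzero value maps to True.

    Images with more than one distinct nonzero value are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    if path.suffix.lower() == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"mask must be single-channel 2D, got shape {arr.shape}")
    values = np.unique(arr)
    nonzero = values[values != 0]
    if nonzero.size > 1:
        raise ValueError(
            f"not a binary mask: distinct values {values.tolist()} in {path}"
        )
    return SegmentationMask(arr > 0, connectivity=connectivity)


# ---------------------------------------------------------------------------
# Annotations / traces (JSON)
# ---------------------------------------------------------------------------


def save_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    doc = {
        "version": ANNOTATION_SCHEMA_VERSION,
        "image": {
            "width": annotations.width,
            "height": annotations.height,
            "pixel_size_um": annotations.pixel_size_um,
        },
        "items": [
            {
                "label": p.label,
                "tags": p.tags,
                "vertices": [[float(x), float(y)] for x, y in p.vertices],
            }
            for p in annotations.items
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_annotations(path: str | Path) -> AnnotationSet:
    """Load an annotation/trace JSON file, validating schema and bounds."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such annotation file: {path}")
    doc = json.loads(path.read_text())
    version = doc.get("version")
    if version != ANNOTATION_SCHEMA_VERSION:
        raise ValueError(
            f"annotation schema version mismatch: file has {version!r}, "
            f"expected {ANNOTATION_SCHEMA_VERSION}"
        )
    img = doc["image"]
    items = []
    for i, raw in enumerate(doc.get("items", [])):
        label = raw.get("label")
        if label not in ANNOTATION_LABELS:
            raise ValueError(
                f"item {i} has unknown label {label!r}; "
                f"expected one of {ANNOTATION_LABELS}"
            )
        items.append(
            Polyline(
                label=label,
                vertices=np.asarray(raw["vertices"], dtype=float),
                tags=dict(raw.get("tags", {})),
            )
        )
    return AnnotationSet(
        width=int(img["width"]),
        height=int(img["height"]),
        items=tuple(items),
        pixel_size_um=float(img.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
    )


# ---------------------------------------------------------------------------
# Measurement tables (CSV)
# ---------------------------------------------------------------------------


def write_measurements(
    records: Sequence, path: str | Path, record_type: type | None = None
) -> None:
    """Write a homogeneous list of measurement dataclasses to CSV.

    Column order follows the dataclass field order (stable across runs);
    floats are written with full round-trip precision. ``record_type`` is
    required when ``records`` is empty so the header can still be emitted.
    """
    records = list(records)
    types = {type(r) for r in records}
    if len(types) > 1:
        raise ValueError(f"mixed record types: {sorted(t.__name__ for t in types)}")
    if record_type is None:
        if not records:
            raise ValueError("record_type is required for an empty record list")
        record_type = types.pop()
    elif records and types != {record_type}:
        raise ValueError(
            f"records of type {types.pop().__name__} do not match "
            f"record_type {record_type.__name__}"
        )
    if not dataclasses.is_dataclass(record_type):
        raise TypeError("record_type must be a dataclass")
    cols = [f.name for f in dataclasses.fields(record_type)]
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
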