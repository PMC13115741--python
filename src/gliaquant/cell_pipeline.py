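"""Single-cell segmentation pipeline and whole-cell morphometry.

The pipeline mirrors a semi-automatic workflow for GFAP-stained astrocytes:
a square region of interest (ROI) is cropped around a manually picked cell
center, segmented with a pre-trained pixel classifier, cleaned by removing
connected components below a size threshold, composited with the raw ROI by
a pixelwise minimum (raw intensities inside the mask, zero outside), and
measured.

Measured parameters per cell: mean GFAP intensity over the mask, area (um^2),
perimeter (um), area-to-perimeter ratio (um), and isoperimetric circularity
4*pi*area/perimeter^2.

The perimeter is a Freeman chain-code boundary length (straight steps count
one pixel, diagonal steps sqrt(2) pixels), traced around every surviving
component and around every hole, matching the particle-analysis convention
of common interactive tools. Note that the chain code runs through pixel
centers, so circularity of very small objects (below the default size
filter) can exceed 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as cc_label

from .imaging_io import (
    IntensityImage,
    SegmentationMask,
    write_image,
    write_mask,
    write_measurements,
)
from .pixel_classifier import PixelClassifierModel, predict_mask

logger = logging.getLogger(__name__)

CONDITIONS = ("scar", "non_scar")
DEFAULT_MIN_AREA_PX = 30  # ~2.7 um^2 at 0.3 um/px


@dataclass(frozen=True)
class CellROI:
    """A square single-cell region of interest in image pixel coordinates."""

    cell_id: str
    center: tuple[int, int]  # (x, y)
    side: int
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.side < 8:
            raise ValueError("ROI side must be at least 8 px")
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS} or empty")

    @property
    def x0(self) -> int:
        return int(self.center[0]) - self.side // 2

    @property
    def y0(self) -> int:
        return int(self.center[1]) - self.side // 2


@dataclass(frozen=True)
class MorphometryRecord:
    """Whole-cell measurements for one segmented astrocyte."""

    cell_id: str
    animal_id: str
    condition: str
    mean_intensity: float
    area_um2: float
    perimeter_um: float
    area_to_perimeter_um: float
    circularity: float
    n_objects: int
    roi_side_px: int
    classifier_id: str


def extract_square_roi(image: IntensityImage, roi: CellROI) -> IntensityImage:
    """Crop the ROI square; the square must lie fully inside the image."""
    h, w = image.shape
    x0, y0 = roi.x0, roi.y0
    x1, y1 = x0 + roi.side, y0 + roi.side
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(
            f"ROI {roi.cell_id}: square [{x0}:{x1}, {y0}:{y1}] exceeds "
            f"image bounds {w}x{h}"
        )
    return IntensityImage(image.pixels[y0:y1, x0:x1].copy(), image.pixel_size_um)


def extract_square_mask(mask: SegmentationMask, roi: CellROI) -> SegmentationMask:
    """Crop a mask with the same geometry as :func:`extract_square_roi`."""
    h, w = mask.shape
    x0, y0 = roi.x0, roi.y0
    x1, y1 = x0 + roi.side, y0 + roi.side
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"ROI {roi.cell_id} exceeds mask bounds")
    return SegmentationMask(mask.pixels[y0:y1, x0:x1].copy(), mask.connectivity)


def filter_objects_by_size(
    mask: SegmentationMask,
    min_area: float,
    connectivity: int | None = None,
    units: str = "px",
    pixel_size_um: float | None = None,
) -> SegmentationMask:
    """Remove connected components smaller than ``min_area``.

    ``min_area`` is a pixel count by default; with ``units="um2"`` it is
    converted using ``pixel_size_um``. All surviving components are kept
    (a cell may legitimately remain multi-component at this resolution).
    """
    if units == "um2":
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for min_area in um^2")
        min_area = min_area / pixel_size_um**2
    elif units != "px":
        raise ValueError("units must be 'px' or 'um2'")
    conn = connectivity if connectivity is not None else mask.connectivity
    labels = cc_label(mask.pixels, connectivity=2 if conn == 8 else 1)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return SegmentationMask(keep[labels], connectivity=conn)


def count_objects(mask: SegmentationMask) -> int:
    labels = cc_label(mask.pixels, connectivity=2 if mask.connectivity == 8 else 1)
    return int(labels.max())


def apply_mask_minimum(roi: IntensityImage, mask: SegmentationMask) -> IntensityImage:
    """Pixelwise minimum of the raw ROI and the {0, MAX} mask image.

    Keeps raw intensities inside the mask and zeroes everything outside;
    idempotent.
    """
    if roi.shape != mask.shape:
        raise ValueError(f"shape mismatch: roi {roi.shape} vs mask {mask.shape}")
    return IntensityImage(
        np.where(mask.pixels, roi.pixels, 0.0), roi.pixel_size_um
    )


# ---------------------------------------------------------------------------
# Chain-code perimeter
# ---------------------------------------------------------------------------

# 8-neighborhood in clockwise order starting north; (dr, dc) offsets.
_N8 = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_STEP = (1.0, math.sqrt(2), 1.0, math.sqrt(2), 1.0, math.sqrt(2), 1.0, math.sqrt(2))


def _trace_boundary_length(padded: np.ndarray, start: tuple[int, int]) -> float:
    """Length of the closed 8-connected boundary chain through pixel centers.

    Moore-neighbor radial sweep: from each boundary pixel, scan the eight
    neighbors clockwise starting just after the direction of the previous
    boundary pixel; terminate when the initial (pixel, move) pair recurs.
    One-pixel spurs are traversed in both directions, as in a chain code.
    """
    cur = start
    back = 6  # pretend we came from the west; start is topmost-leftmost
    length = 0.0
    first_pair = None
    while True:
        for k in range(1, 9):
            d = (back + k) % 8
            nb = (cur[0] + _N8[d][0], cur[1] + _N8[d][1])
            if padded[nb]:
                break
        else:  # isolated pixel
            return 0.0
        if first_pair is None:
            first_pair = (cur, d)
        elif (cur, d) == first_pair:
            break
        length += _STEP[d]
        back = (d + 4) % 8
        cur = nb
    return length


def _single_object_perimeter(obj: np.ndarray) -> float:
    if obj.sum() == 1:
        return 4.0  # outline of one pixel square
    padded = np.pad(obj, 1)
    rs, cs = np.nonzero(padded)
    length = _trace_boundary_length(padded, (int(rs[0]), int(cs[0])))
    return length if length > 0 else 4.0


def chain_code_perimeter(mask: SegmentationMask) -> float:
    """Total chain-code boundary length (in pixels), holes included.

    Every connected component contributes its outer boundary; every hole
    contributes the boundary of the hole region, traced the same way.
    """
    conn = 2 if mask.connectivity == 8 else 1
    labels = cc_label(mask.pixels, connectivity=conn)
    total = 0.0
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        total += _single_object_perimeter(comp)
        holes = binary_fill_holes(comp) & ~comp
        if holes.any():
            hole_labels = cc_label(holes, connectivity=1)
            for h in range(1, hole_labels.max() + 1):
                total += _single_object_perimeter(hole_labels == h)
    return total


def measure_cell(
    roi: IntensityImage,
    mask: SegmentationMask,
    cell_id: str = "",
    animal_id: str = "",
    condition: str = "",
    classifier_id: str = "",
) -> MorphometryRecord:
    """Measure one cell: intensity, area, perimeter, a/p ratio, circularity.

    Mean intensity is taken over mask-true pixels of the raw ROI only, so it
    does not depend on the ROI size. All surviving components contribute to
    every measurement.
    """
    if roi.shape != mask.shape:
        raise ValueError("roi and mask shapes differ")
    if not mask.pixels.any():
        raise ValueError("no object to measure (empty mask)")
    ps = roi.pixel_size_um
    area_px = float(mask.pixels.sum())
    perimeter_px = chain_code_perimeter(mask)
    area_um2 = area_px * ps**2
    perimeter_um = perimeter_px * ps
    return MorphometryRecord(
        cell_id=cell_id,
        animal_id=animal_id,
        condition=condition,
        mean_intensity=float(roi.pixels[mask.pixels].mean()),
        area_um2=area_um2,
        perimeter_um=perimeter_um,
        area_to_perimeter_um=area_um2 / perimeter_um,
        circularity=4.0 * math.pi * area_um2 / perimeter_um**2,
        n_objects=count_objects(mask),
        roi_side_px=mask.shape[0],
        classifier_id=classifier_id,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROIFailure:
    cell_id: str
    reason: str


@dataclass
class PipelineResult:
    records: list[MorphometryRecord] = field(default_factory=list)
    failures: list[ROIFailure] = field(default_factory=list)
    masks: dict[str, SegmentationMask] = field(default_factory=dict)
    composites: dict[str, IntensityImage] = field(default_factory=dict)


def run_pipeline(
    image: IntensityImage,
    rois: Sequence[CellROI],
    model: PixelClassifierModel,
    min_area_px: float = DEFAULT_MIN_AREA_PX,
    prob_threshold: float = 0.5,
    connectivity: int = 8,
    classifier_id: str = "",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Crop, segment, size-filter, composite and measure every ROI.

    ROIs whose mask is empty after filtering are reported as failures, not
    silently dropped. With ``out_dir``, masks and composites are written as
    TIFFs and the measurements as CSV.
    """
    result = PipelineResult()
    for roi in rois:
        try:
            crop = extract_square_roi(image, roi)
            raw_mask = predict_mask(model, crop, prob_threshold=prob_threshold)
            mask = filter_objects_by_size(
                SegmentationMask(raw_mask.pixels, connectivity), min_area_px
            )
            if not mask.pixels.any():
                raise ValueError("empty mask after size filtering")
            composite = apply_mask_minimum(crop, mask)
            record = measure_cell(
                crop,
                mask,
                cell_id=roi.cell_id,
                animal_id=roi.animal_id,
                condition=roi.condition,
                classifier_id=classifier_id,
            )
        except ValueError as exc:
            logger.warning("ROI %s failed: %s", roi.cell_id, exc)
            result.failures.append(ROIFailure(roi.cell_id, str(exc)))
            continue
        result.records.append(record)
        result.masks[roi.cell_id] = mask
        result.composites[roi.cell_id] = composite
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_measurements(
            result.records, out_dir / "measurements.csv", MorphometryRecord
        )
        for cid, mask in result.masks.items():
            write_mask(mask, out_dir / f"{cid}_mask.tif")
        for cid, comp in result.composites.items():
            write_image(comp, out_dir / f"{cid}_composite.tif")
    return result
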