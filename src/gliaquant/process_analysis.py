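"""GFAP intensity profiling along traced astrocytic processes.

A process trace is an ordered polyline whose first vertex is the proximal
(soma-side) end. The trace is resampled at fixed arc-length spacing (1 px by
default) and intensities are read off the raw image by bilinear
interpolation (nearest-pixel sampling is available for exactness checks).
The profile summarizes the whole process and two 10-sample compartments:
the proximal segment (first 10 samples, 3 um at 0.3 um/px) and the distal
segment (last 10 samples). The distal-to-proximal ratio is a scale-invariant
descriptor of how GFAP signal is distributed along the process; proximal
enrichment (as seen in reactive astrocytes of the glial scar) lowers it.

Traces shorter than two disjoint compartments (20 samples) are flagged:
their whole-process mean is still computed but compartment values are null
and they are excluded from ratio summaries, while still counting toward the
per-cell process count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .imaging_io import IntensityImage, SegmentationMask

COMPARTMENT_PX = 10
MIN_COMPARTMENT_TRACE_SAMPLES = 2 * COMPARTMENT_PX


@dataclass(frozen=True)
class ProcessTrace:
    """An ordered process polyline; first vertex = proximal (soma) end."""

    cell_id: str
    process_id: str
    vertices: np.ndarray  # (n, 2) float array of (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("trace needs at least 2 (x, y) vertices")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class ProcessProfile:
    """Intensity summary of one traced process."""

    cell_id: str
    process_id: str
    mean_all: float
    mean_distal: float | None
    mean_proximal: float | None
    distal_to_proximal_ratio: float | None
    length_um: float
    n_samples: int
    flags: str = ""


def resample_trace(
    trace: ProcessTrace | np.ndarray, spacing: float = 1.0
) -> np.ndarray:
    """Resample a polyline at exact arc-length multiples of ``spacing``.

    Returns ``floor(L / spacing) + 1`` points starting at the proximal end.
    If the spacing exceeds the total length, the two endpoints are returned.
    """
    vertices = trace.vertices if isinstance(trace, ProcessTrace) else np.asarray(trace, float)
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("zero-length polyline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = int(np.floor(total / spacing)) + 1
    if n < 2:
        return np.vstack([vertices[0], vertices[-1]])
    s = np.arange(n) * spacing
    xs = np.interp(s, cum, vertices[:, 0])
    ys = np.interp(s, cum, vertices[:, 1])
    return np.column_stack([xs, ys])


def _sample_intensities(
    image: IntensityImage, points: np.ndarray, sampler: str
) -> np.ndarray:
    if sampler == "bilinear":
        return map_coordinates(
            image.pixels, [points[:, 1], points[:, 0]], order=1, mode="nearest"
        )
    if sampler == "nearest":
        rows = np.clip(np.round(points[:, 1]).astype(int), 0, image.shape[0] - 1)
        cols = np.clip(np.round(points[:, 0]).astype(int), 0, image.shape[1] - 1)
        return image.pixels[rows, cols]
    raise ValueError("sampler must be 'bilinear' or 'nearest'")


def compartment_span_um(
    compartment_px: int = COMPARTMENT_PX,
    spacing: float = 1.0,
    pixel_size_um: float = 0.3,
) -> float:
    """Physical span of one compartment (10 samples at 0.3 um/px -> 3 um)."""
    return compartment_px * spacing * pixel_size_um


def profile_process(
    image: IntensityImage,
    trace: ProcessTrace,
    compartment_px: int = COMPARTMENT_PX,
    spacing: float = 1.0,
    sampler: str = "bilinear",
) -> ProcessProfile:
    """Profile one traced process on the raw image.

    Profiles are taken on the raw image (not the mask-composited one) so the
    compartment ratio is not censored where segmentation misses thin distal
    stretches.
    """
    points = resample_trace(trace, spacing=spacing)
    values = _sample_intensities(image, points, sampler)
    n = len(points)
    flags = []
    mean_all = float(values.mean())
    length_um = (n - 1) * spacing * image.pixel_size_um
    mean_proximal = mean_distal = ratio = None
    if n < 2 * compartment_px:
        flags.append("too_short")
    else:
        mean_proximal = float(values[:compartment_px].mean())
        mean_distal = float(values[-compartment_px:].mean())
        if mean_proximal > 0:
            ratio = mean_distal / mean_proximal
        else:
            flags.append("zero_proximal")
    return ProcessProfile(
        cell_id=trace.cell_id,
        process_id=trace.process_id,
        mean_all=mean_all,
        mean_distal=mean_distal,
        mean_proximal=mean_proximal,
        distal_to_proximal_ratio=ratio,
        length_um=length_um,
        n_samples=n,
        flags=";".join(flags),
    )


@dataclass(frozen=True)
class CellProcessSummary:
    """Per-cell process-tree summary."""

    cell_id: str
    mean_length_um: float
    n_processes: int
    mean_distal_to_proximal_ratio: float | None


def summarize_processes(
    profiles: Sequence[ProcessProfile],
) -> list[CellProcessSummary]:
    """Per-cell mean process length, process count and mean compartment ratio.

    Flagged-short traces count toward the process count and length but are
    excluded from the compartment ratio.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    groups: dict[str, list[ProcessProfile]] = defaultdict(list)
    for p in profiles:
        groups[p.cell_id].append(p)
    out = []
    for cell_id, ps in groups.items():
        ratios = [
            p.distal_to_proximal_ratio
            for p in ps
            if p.distal_to_proximal_ratio is not None
        ]
        out.append(
            CellProcessSummary(
                cell_id=cell_id,
                mean_length_um=float(np.mean([p.length_um for p in ps])),
                n_processes=len(ps),
                mean_distal_to_proximal_ratio=(
                    float(np.mean(ratios)) if ratios else None
                ),
            )
        )
    return out


def mask_coverage_counts(
    traces: Sequence[ProcessTrace],
    mask: SegmentationMask,
    spacing: float = 1.0,
) -> tuple[int, int]:
    """(hits, total) resampled trace points whose nearest pixel is mask-true."""
    if not traces:
        raise ValueError("no traces given")
    hits = 0
    total = 0
    h, w = mask.shape
    for trace in traces:
        pts = resample_trace(trace, spacing=spacing)
        rows = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        cols = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        hits += int(mask.pixels[rows, cols].sum())
        total += len(pts)
    return hits, total


def mask_coverage_fraction(
    traces: Sequence[ProcessTrace],
    mask: SegmentationMask,
    spacing: float = 1.0,
) -> float:
    """Fraction of resampled trace points whose nearest pixel is mask-true.

    Pooling over traces makes this a length-weighted estimate of how much of
    the manually traced process tree the segmentation mask captures.
    """
    hits, total = mask_coverage_counts(traces, mask, spacing=spacing)
    return hits / total
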