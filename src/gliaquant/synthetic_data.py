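"""Synthetic GFAP-like astrocyte scenes with full ground truth.

No imaging data is distributed with the package, so every pipeline stage is
exercised on generated scenes that emulate the observables of GFAP-stained
astrocytes in peri-implant scar versus distant cortex:

* a cell is a bright soma disk plus several correlated-random-walk processes
  of finite width, with intensity decaying exponentially along each process
  (``I(s) = I0 * exp(-s / lambda)``) and a proximal-enrichment factor
  ``rho >= 1`` multiplying the proximal third — the simplest intensity model
  that can raise both compartments while lowering the distal-to-proximal
  ratio;
* a faint wide halo (a blurred copy of the cell at low amplitude) emulates
  out-of-focus light, so background pixels next to a cell are brighter than
  background far away — which is what makes the placement of background
  scribbles matter;
* scar scenes add distractor cells crowding the ROI margins, giving the
  object-size filter realistic work;
* a cohort has per-animal multiplicative log-normal jitter (shared between
  conditions) and per-cell jitter, so paired per-animal differences have
  realistic variance at N = 4 animals.

Everything is deterministic under the master seed. Ground-truth masks are
the noiseless, halo-free render thresholded at zero; ground-truth traces are
returned exactly as generated, proximal vertex first (just inside the soma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .cell_pipeline import CellROI
from .imaging_io import (
    AnnotationSet,
    IntensityImage,
    Polyline,
    SegmentationMask,
    save_annotations,
    write_image,
    write_mask,
)
from .process_analysis import ProcessTrace, resample_trace

STRATEGIES = (
    "rule_compliant",
    "rv_core_only",
    "rv_far_background",
    "rv_scar_trained",
)

_HALO_AMPLITUDE = 0.2
_HALO_SIGMA = 10.0
_WALK_STEP = 2.0
_WALK_CURL = 0.25
_MAX_WALK_RETRIES = 50


@dataclass(frozen=True)
class AstrocyteParams:
    """Generative parameters of one synthetic astrocyte."""

    soma_radius: float = 6.0  # px
    n_processes: int = 5
    process_length_mean: float = 32.0  # px
    # branching is opt-in: branch traces start on their parent process,
    # not inside the soma, so they are excluded from the soma-origin
    # guarantee that holds for all primary traces
    branch_prob: float = 0.0
    intensity_soma: float = 120.0  # AU (I0)
    decay_length: float = 25.0  # px (lambda)
    proximal_enrichment: float = 1.0  # rho >= 1
    process_width: float = 2.5  # px

    def __post_init__(self) -> None:
        if min(
            self.soma_radius,
            self.process_length_mean,
            self.intensity_soma,
            self.decay_length,
            self.process_width,
        ) <= 0:
            raise ValueError("all astrocyte parameters must be positive")
        if self.n_processes < 1:
            raise ValueError("n_processes must be >= 1")
        if self.proximal_enrichment < 1:
            raise ValueError("proximal_enrichment must be >= 1")


@dataclass(frozen=True)
class NoiseConfig:
    gaussian_sd: float = 5.0
    background_level: float = 10.0


@dataclass(frozen=True)
class RenderedCell:
    image: np.ndarray  # noiseless cell image incl. halo
    mask: np.ndarray  # ground-truth boolean mask (halo-free render > 0)
    traces: list[np.ndarray]  # (n, 2) (x, y) polylines, proximal first


def _random_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    length: float,
    shape: tuple[int, int],
    margin: float = 2.0,
) -> np.ndarray | None:
    """Correlated random walk; None if it would leave the canvas."""
    h, w = shape
    pts = [start.copy()]
    pos = start.copy()
    travelled = 0.0
    while travelled < length:
        heading += rng.normal(0.0, _WALK_CURL)
        step = min(_WALK_STEP, length - travelled)
        pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
        if not (margin <= pos[0] < w - margin and margin <= pos[1] < h - margin):
            return None
        pts.append(pos.copy())
        travelled += step
    return np.array(pts)


def _stamp_process(
    canvas: np.ndarray,
    poly: np.ndarray,
    params: AstrocyteParams,
) -> None:
    """Max-composite a process onto the canvas with exp-decay intensity."""
    pts = resample_trace(poly, spacing=0.5)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
    radius = max(params.process_width / 2.0, 0.5)
    for i, (x, y) in enumerate(pts):
        s = i * 0.5
        value = params.intensity_soma * math.exp(-s / params.decay_length)
        if s < seg / 3.0:
            value *= params.proximal_enrichment
        rr, cc = draw_disk((y, x), radius, shape=canvas.shape)
        np.maximum.at(canvas, (rr, cc), value)


def render_astrocyte(
    params: AstrocyteParams,
    seed: int | np.random.SeedSequence,
    canvas: tuple[int, int] = (128, 128),
    center: tuple[float, float] | None = None,
    halo_amplitude: float = _HALO_AMPLITUDE,
    halo_sigma: float = _HALO_SIGMA,
) -> RenderedCell:
    """Render one astrocyte: soma disk + processes, deterministic per seed.

    Each trace starts just inside the soma boundary (its proximal end) and
    follows the process outward. A process whose walk would leave the canvas
    is regenerated with a bounded number of retries.
    """
    rng = np.random.default_rng(seed)
    h, w = canvas
    cx, cy = center if center is not None else (w / 2.0, h / 2.0)
    core = np.zeros((h, w), dtype=float)
    rr, cc = draw_disk((cy, cx), params.soma_radius, shape=(h, w))
    core[rr, cc] = params.intensity_soma

    traces: list[np.ndarray] = []
    base = rng.uniform(0, 2 * math.pi)
    for k in range(params.n_processes):
        heading0 = base + 2 * math.pi * k / params.n_processes
        poly = None
        for attempt in range(_MAX_WALK_RETRIES):
            # keep the nominal direction first; fall back to free directions
            # for cells near the canvas edge (e.g. scar distractors)
            if attempt < 5:
                heading = heading0 + rng.normal(0.0, 0.3)
            else:
                heading = rng.uniform(0.0, 2 * math.pi)
            length = params.process_length_mean * rng.lognormal(0.0, 0.2)
            start = np.array(
                [
                    cx + (params.soma_radius - 1.0) * math.cos(heading),
                    cy + (params.soma_radius - 1.0) * math.sin(heading),
                ]
            )
            poly = _random_walk(rng, start, heading, length, (h, w))
            if poly is not None:
                break
        if poly is None:
            raise RuntimeError(
                f"process escaped the {w}x{h} canvas after "
                f"{_MAX_WALK_RETRIES} retries"
            )
        traces.append(poly)
        # occasional side branch, itself a (shorter) process
        if rng.uniform() < params.branch_prob and len(poly) >= 6:
            j = int(rng.integers(2, len(poly) - 2))
            direction = poly[j + 1] - poly[j]
            branch_heading = math.atan2(direction[1], direction[0])
            branch_heading += rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
            branch = _random_walk(
                rng,
                poly[j].copy(),
                branch_heading,
                params.process_length_mean * 0.5 * rng.lognormal(0.0, 0.2),
                (h, w),
            )
            if branch is not None and len(branch) >= 2:
                traces.append(branch)

    for poly in traces:
        _stamp_process(core, poly, params)
    image = core.copy()
    if halo_amplitude > 0:
        image += halo_amplitude * gaussian_filter(core, halo_sigma)
    return RenderedCell(image=image, mask=core > 0, traces=traces)


@dataclass(frozen=True)
class SyntheticScene:
    """An image with ground truth for the cells it contains."""

    image: IntensityImage
    noiseless: np.ndarray
    cell_masks: tuple[SegmentationMask, ...]
    cell_traces: tuple[tuple[np.ndarray, ...], ...]
    cell_centers: tuple[tuple[float, float], ...]
    cell_params: tuple[AstrocyteParams, ...]
    n_distractors: int
    seed: int | None = None


def generate_scene(
    cells: Sequence[tuple[AstrocyteParams, tuple[float, float]]],
    distractors: Sequence[tuple[AstrocyteParams, tuple[float, float]]] = (),
    noise: NoiseConfig = NoiseConfig(),
    seed: int | np.random.SeedSequence = 0,
    canvas: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.3,
) -> SyntheticScene:
    """Sum cell renders, add background and Gaussian noise (clipped at 0).

    Ground truth (masks, traces) is preserved from the pre-noise renders of
    the focal ``cells``; ``distractors`` contribute only to the image.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(cells) + len(distractors) + 1)
    accum = np.zeros(canvas, dtype=float)
    masks, traces, centers, plist = [], [], [], []
    for child, (params, center) in zip(children, cells):
        rc = render_astrocyte(params, child, canvas=canvas, center=center)
        accum += rc.image
        masks.append(SegmentationMask(rc.mask))
        traces.append(tuple(rc.traces))
        centers.append(tuple(center))
        plist.append(params)
    for child, (params, center) in zip(children[len(cells):], distractors):
        accum += render_astrocyte(params, child, canvas=canvas, center=center).image
    noiseless = accum + noise.background_level
    noise_rng = np.random.default_rng(children[-1])
    img = noiseless + noise_rng.normal(0.0, noise.gaussian_sd, size=canvas)
    np.clip(img, 0.0, None, out=img)
    return SyntheticScene(
        image=IntensityImage(img, pixel_size_um),
        noiseless=noiseless,
        cell_masks=tuple(masks),
        cell_traces=tuple(traces),
        cell_centers=tuple(centers),
        cell_params=tuple(plist),
        n_distractors=len(distractors),
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study design of a synthetic scar vs non-scar cohort.

    Defaults emulate the scale of the study design the pipeline targets:
    4 animals, >= 10 cells per condition per animal (13 x 2 x 4 = 104 cells,
    on the order of 100 cells), with scar cells drawn brighter
    (``k_intensity``), larger (``k_area`` on soma area), longer-processed
    (``k_length``), with ``delta_processes`` extra processes and stronger
    proximal enrichment (``rho_scar``).
    """

    n_animals: int = 4
    cells_per_condition: int = 13
    k_intensity: float = 1.3
    k_area: float = 1.5
    k_length: float = 1.5
    delta_processes: int = 2
    rho_scar: float = 1.5
    rho_nonscar: float = 1.0
    n_distractors_scar: int = 3
    n_distractors_nonscar: int = 0
    animal_jitter_sigma: float = 0.08
    cell_jitter_sigma: float = 0.10
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    base_params: AstrocyteParams = field(default_factory=AstrocyteParams)
    pixel_size_um: float = 0.3
    canvas: int = 128
    roi_side: int = 112
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_intensity, self.k_area, self.k_length) <= 0:
            raise ValueError("multipliers must be positive")
        if min(self.rho_scar, self.rho_nonscar) < 1:
            raise ValueError("proximal enrichment must be >= 1")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """A null cohort: conditions are exchangeable by construction."""
        return cls(
            k_intensity=1.0,
            k_area=1.0,
            k_length=1.0,
            delta_processes=0,
            rho_scar=1.0,
            rho_nonscar=1.0,
            n_distractors_scar=0,
            n_distractors_nonscar=0,
            seed=seed,
            **overrides,
        )


@dataclass(frozen=True)
class SyntheticCell:
    """One cohort cell: its scene, ROI and ground truth."""

    cell_id: str
    animal_id: str
    condition: str
    image: IntensityImage
    mask: SegmentationMask  # ground truth, full canvas
    traces: tuple[ProcessTrace, ...]
    roi: CellROI
    params: AstrocyteParams


@dataclass(frozen=True)
class Cohort:
    cells: tuple[SyntheticCell, ...]
    config: CohortConfig

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "animal_id": c.animal_id,
                    "condition": c.condition,
                    "roi_center_x": c.roi.center[0],
                    "roi_center_y": c.roi.center[1],
                    "roi_side": c.roi.side,
                    "soma_radius": c.params.soma_radius,
                    "n_processes": c.params.n_processes,
                    "process_length_mean": c.params.process_length_mean,
                    "intensity_soma": c.params.intensity_soma,
                    "proximal_enrichment": c.params.proximal_enrichment,
                }
                for c in self.cells
            ]
        )

    def write(self, out_dir: str | Path) -> None:
        """Write images, masks, traces and the manifest to a directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for c in self.cells:
            write_image(c.image, out_dir / f"{c.cell_id}.tif")
            write_mask(c.mask, out_dir / f"{c.cell_id}_mask.tif")
            h, w = c.image.shape
            items = [
                Polyline(
                    "trace",
                    np.clip(t.vertices, 0, [w - 1, h - 1]),
                    {"cell_id": c.cell_id, "process_id": t.process_id},
                )
                for t in c.traces
            ]
            save_annotations(
                AnnotationSet(w, h, tuple(items), c.image.pixel_size_um),
                out_dir / f"{c.cell_id}_traces.json",
            )
        self.manifest().to_csv(out_dir / "manifest.csv", index=False)


def _cell_params(
    cfg: CohortConfig, rng: np.random.Generator, scar: bool, jitters: dict
) -> AstrocyteParams:
    cj = cfg.cell_jitter_sigma
    base = cfg.base_params
    k_int = cfg.k_intensity if scar else 1.0
    k_area = cfg.k_area if scar else 1.0
    k_len = cfg.k_length if scar else 1.0
    n_proc = base.n_processes + (cfg.delta_processes if scar else 0)
    n_proc = max(1, n_proc + int(rng.integers(-1, 2)))
    return replace(
        base,
        intensity_soma=base.intensity_soma
        * k_int
        * jitters["intensity"]
        * rng.lognormal(0.0, cj),
        soma_radius=base.soma_radius
        * math.sqrt(k_area)
        * jitters["size"]
        * rng.lognormal(0.0, cj / 2),
        process_length_mean=base.process_length_mean
        * k_len
        * jitters["length"]
        * rng.lognormal(0.0, cj),
        n_processes=n_proc,
        proximal_enrichment=cfg.rho_scar if scar else cfg.rho_nonscar,
    )


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate the full cohort: one scene per cell, scar cells crowded.

    Per-animal log-normal jitter (one factor per animal for intensity, size
    and process length, shared between conditions) induces realistic paired
    variance; per-cell jitter adds within-animal spread.
    """
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    scene_seeds = iter(
        np.random.SeedSequence(config.seed + 1).spawn(
            config.n_animals * 2 * config.cells_per_condition
        )
    )
    half = config.canvas / 2.0
    cells = []
    for a in range(config.n_animals):
        jitters = {
            key: rng.lognormal(0.0, config.animal_jitter_sigma)
            for key in ("intensity", "size", "length")
        }
        for condition in ("non_scar", "scar"):
            scar = condition == "scar"
            n_dist = (
                config.n_distractors_scar if scar else config.n_distractors_nonscar
            )
            for i in range(config.cells_per_condition):
                params = _cell_params(config, rng, scar, jitters)
                center = (
                    half + rng.uniform(-5, 5),
                    half + rng.uniform(-5, 5),
                )
                distractors = []
                for _ in range(n_dist):
                    angle = rng.uniform(0, 2 * math.pi)
                    radius = rng.uniform(0.35, 0.48) * config.canvas
                    dc = (
                        float(np.clip(center[0] + radius * math.cos(angle), 8, config.canvas - 8)),
                        float(np.clip(center[1] + radius * math.sin(angle), 8, config.canvas - 8)),
                    )
                    distractors.append((_cell_params(config, rng, scar, jitters), dc))
                cell_id = f"a{a}_{condition}_{i:02d}"
                scene = generate_scene(
                    [(params, center)],
                    distractors=distractors,
                    noise=config.noise,
                    seed=next(scene_seeds),
                    canvas=(config.canvas, config.canvas),
                    pixel_size_um=config.pixel_size_um,
                )
                traces = tuple(
                    ProcessTrace(cell_id, f"p{j}", poly)
                    for j, poly in enumerate(scene.cell_traces[0])
                )
                roi = CellROI(
                    cell_id=cell_id,
                    center=(int(half), int(half)),
                    side=config.roi_side,
                    animal_id=f"animal_{a}",
                    condition=condition,
                )
                cells.append(
                    SyntheticCell(
                        cell_id=cell_id,
                        animal_id=f"animal_{a}",
                        condition=condition,
                        image=scene.image,
                        mask=scene.cell_masks[0],
                        traces=traces,
                        roi=roi,
                        params=params,
                    )
                )
    cohort = Cohort(cells=tuple(cells), config=config)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


# ---------------------------------------------------------------------------
# Scribble strategies
# ---------------------------------------------------------------------------


def _longest_trace(cell: SyntheticCell) -> ProcessTrace:
    def arclen(t: ProcessTrace) -> float:
        return float(np.linalg.norm(np.diff(t.vertices, axis=0), axis=1).sum())

    return max(cell.traces, key=arclen)


def _clip_poly(poly: np.ndarray, w: int, h: int) -> np.ndarray:
    return np.clip(poly, [0, 0], [w - 1, h - 1])


def _offset_polyline(
    poly: np.ndarray, gap: float, others: Sequence[np.ndarray], w: int, h: int
) -> np.ndarray:
    """Offset a polyline perpendicular by +-gap, picking the clearer side."""
    d = np.gradient(poly, axis=0)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = d / norms
    normal = np.column_stack([-unit[:, 1], unit[:, 0]])
    candidates = [poly + gap * normal, poly - gap * normal]
    if others:
        cloud = np.vstack(others)

        def clearance(cand: np.ndarray) -> float:
            dists = np.linalg.norm(
                cand[:, None, :] - cloud[None, :, :], axis=2
            )
            return float(dists.min())

        candidates.sort(key=clearance, reverse=True)
    return _clip_poly(candidates[0], w, h)


def generate_scribbles(
    cell: SyntheticCell,
    strategy: str,
    seed: int = 0,
    gap: float = 6.0,
) -> AnnotationSet:
    """Programmatic foreground/background scribbles for one training cell.

    ``rule_compliant`` follows all four annotation rules of thumb: drawn on a
    non-scar cell, the foreground line runs through the cell body and the
    longest process (so it contains both bright and dim pixels), and the
    background line runs alongside it at a small gap.  Each ``rv_*``
    strategy violates exactly one rule:

    * ``rv_core_only`` — foreground restricted to the bright soma core;
    * ``rv_far_background`` — background drawn at the farthest image corner;
    * ``rv_scar_trained`` — rule-compliant geometry, but on a crowded scar
      cell.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected {STRATEGIES}")
    if strategy == "rv_scar_trained" and cell.condition != "scar":
        raise ValueError("rv_scar_trained requires a scar cell")
    if strategy != "rv_scar_trained" and cell.condition != "non_scar":
        raise ValueError(f"{strategy} requires a non-scar cell")

    h, w = cell.image.shape
    # the current strategies are deterministic geometric constructions;
    # `seed` is part of the interface for randomized strategy variants
    longest = _longest_trace(cell)
    v0 = longest.vertices[0]
    direction = longest.vertices[1] - v0
    unit = direction / max(np.linalg.norm(direction), 1e-9)
    # soma center sits one radius behind the proximal trace vertex
    soma_center = v0 - unit * (cell.params.soma_radius - 1.0)
    others = [t.vertices for t in cell.traces if t is not longest]
    tags = {"strategy": strategy, "cell_id": cell.cell_id}

    if strategy == "rv_core_only":
        r = cell.params.soma_radius
        normal = np.array([-unit[1], unit[0]])
        # a cross of two chords inside the bright soma core
        fg = np.vstack(
            [
                soma_center - 0.7 * r * unit,
                soma_center + 0.7 * r * unit,
                soma_center,
                soma_center - 0.7 * r * normal,
                soma_center + 0.7 * r * normal,
            ]
        )
        # background alongside the soma, just outside it
        bg = _offset_polyline(
            np.vstack([soma_center - 2.0 * r * unit, soma_center + 2.0 * r * unit]),
            r + gap / 2.0,
            others,
            w,
            h,
        )
    else:
        through_body = soma_center - unit * (cell.params.soma_radius * 0.8)
        fg = np.vstack([through_body, longest.vertices])
        if strategy == "rv_far_background":
            # an L-shaped line hugging the farthest image corner
            corners = np.array(
                [[2.0, 2.0], [w - 3.0, 2.0], [2.0, h - 3.0], [w - 3.0, h - 3.0]]
            )
            far = corners[
                np.argmax(np.linalg.norm(corners - soma_center, axis=1))
            ]
            along_x = 12.0 if far[0] < w / 2 else -12.0
            along_y = 12.0 if far[1] < h / 2 else -12.0
            bg = np.vstack(
                [far + [0.0, along_y], far, far + [along_x, 0.0]]
            )
            bg = _clip_poly(bg, w, h)
        else:
            bg = _offset_polyline(fg, gap, others, w, h)
        fg = _clip_poly(fg, w, h)

    items = (
        Polyline("foreground", fg, tags),
        Polyline("background", bg, {**tags, "role": "background"}),
    )
    return AnnotationSet(w, h, items, cell.image.pixel_size_um)
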