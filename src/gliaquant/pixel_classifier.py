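"""Scribble-trained random-forest pixel classification.

This re-implements the shallow-learning core used by trainable-segmentation
tools: every pixel is described by a stack of hand-crafted filter responses
(smoothed intensity, derivatives, local order statistics, each at several
scales), a random forest is trained on the pixels covered by sparse
foreground/background scribbles, and the forest's per-pixel foreground
probability is thresholded into a binary mask.

The feature families and scales default to the conventional
trainable-segmentation set (identity plus Gaussian, difference-of-Gaussians,
gradient magnitude, Laplacian, Hessian eigenvalues, and local min/max/mean at
scales 1, 2, 4, 8 px); all filters use reflection padding at the image
border, so predictions are translation-equivariant away from borders.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import disk, binary_dilation
from sklearn.ensemble import RandomForestClassifier

from .imaging_io import AnnotationSet, IntensityImage, SegmentationMask

MODEL_SCHEMA_VERSION = 1
MODEL_FORMAT = "gliaquant-model"

FEATURE_FAMILIES = (
    "identity",
    "gaussian",
    "difference_of_gaussians",
    "gradient_magnitude",
    "laplacian",
    "hessian_eigenvalues",
    "local_min",
    "local_max",
    "local_mean",
)

_BORDER_MODE = "reflect"


@dataclass(frozen=True)
class FeatureConfig:
    """Which filter families to compute, and at which scales (in pixels)."""

    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    families: tuple[str, ...] = FEATURE_FAMILIES

    def __post_init__(self) -> None:
        scales = tuple(float(s) for s in self.scales)
        if not scales or any(s <= 0 for s in scales):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        families = tuple(self.families)
        unknown = set(families) - set(FEATURE_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if not families:
            raise ValueError("at least one feature family must be enabled")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "families", families)


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel feature planes: shape (H, W, n_features), with plane names."""

    values: np.ndarray
    names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.values.shape[-1]


def _gauss_kernel(s: float, order: int) -> np.ndarray:
    """Sampled Gaussian (derivative) kernel, truncated at 4 sigma.

    The second-derivative kernel is shifted to exact zero sum so that
    second-order features respond exactly zero to constant images (the
    truncated analytic kernel leaves a ~exp(-8) residual otherwise).
    """
    radius = max(int(4 * s + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / s) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        return -x / s**2 * g
    k = (x**2 - s**2) / s**4 * g
    return k - k.sum() / k.size


def _sep_filter(img: np.ndarray, s: float, order_rc: tuple[int, int]) -> np.ndarray:
    out = ndi.correlate1d(img, _gauss_kernel(s, order_rc[0]), axis=0, mode=_BORDER_MODE)
    return ndi.correlate1d(out, _gauss_kernel(s, order_rc[1]), axis=1, mode=_BORDER_MODE)


def _family_planes(img: np.ndarray, family: str, s: float):
    """Yield (suffix, plane) pairs for one family at one scale."""
    if family == "gaussian":
        yield "", ndi.gaussian_filter(img, s, mode=_BORDER_MODE)
    elif family == "difference_of_gaussians":
        yield "", (
            ndi.gaussian_filter(img, s, mode=_BORDER_MODE)
            - ndi.gaussian_filter(img, 2 * s, mode=_BORDER_MODE)
        )
    elif family == "gradient_magnitude":
        yield "", ndi.gaussian_gradient_magnitude(img, s, mode=_BORDER_MODE)
    elif family == "laplacian":
        yield "", _sep_filter(img, s, (2, 0)) + _sep_filter(img, s, (0, 2))
    elif family == "hessian_eigenvalues":
        hrr = _sep_filter(img, s, (2, 0))
        hcc = _sep_filter(img, s, (0, 2))
        hrc = _sep_filter(img, s, (1, 1))
        half_trace = 0.5 * (hrr + hcc)
        root = np.sqrt(0.25 * (hrr - hcc) ** 2 + hrc**2)
        yield "_1", half_trace + root
        yield "_2", half_trace - root
    else:
        size = int(2 * round(s) + 1)
        if family == "local_min":
            yield "", ndi.minimum_filter(img, size=size, mode=_BORDER_MODE)
        elif family == "local_max":
            yield "", ndi.maximum_filter(img, size=size, mode=_BORDER_MODE)
        elif family == "local_mean":
            yield "", ndi.uniform_filter(img, size=size, mode=_BORDER_MODE)
        else:  # pragma: no cover - guarded by FeatureConfig
            raise ValueError(f"unknown family {family!r}")


def compute_feature_stack(image: IntensityImage, config: FeatureConfig) -> FeatureStack:
    """Compute the per-pixel feature stack for an image.

    The identity plane (the raw image) is always included; every other
    enabled family contributes one plane per scale (two for the Hessian
    eigenvalues). Deterministic for identical (image, config).
    """
    img = image.pixels.astype(np.float64)
    scaled = [f for f in config.families if f != "identity"]
    if scaled and max(config.scales) > min(img.shape) / 2:
        raise ValueError(
            f"largest scale {max(config.scales)} exceeds half the smallest "
            f"image dimension ({min(img.shape)})"
        )
    planes = [img]
    names = ["identity"]
    for family in scaled:
        for s in config.scales:
            for suffix, plane in _family_planes(img, family, s):
                planes.append(plane)
                names.append(f"{family}{suffix}@{s:g}")
    values = np.stack(planes, axis=-1).astype(np.float32)
    return FeatureStack(values=values, names=tuple(names))


# ---------------------------------------------------------------------------
# Scribble rasterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScribbleSamples:
    """Disjoint (row, col) pixel sample sets for the two scribble classes."""

    foreground: np.ndarray  # (n_fg, 2) int array of (row, col)
    background: np.ndarray
    n_conflicts: int


def _rasterize_polylines(polylines, shape, width: int) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    for poly in polylines:
        v = np.round(poly.vertices).astype(int)
        for (x0, y0), (x1, y1) in zip(v[:-1], v[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            canvas[rr[keep], cc[keep]] = True
    radius = (width - 1) // 2
    if radius > 0:
        canvas = binary_dilation(canvas, disk(radius))
    return canvas


def rasterize_scribbles(annotations: AnnotationSet, width: int = 1) -> ScribbleSamples:
    """Rasterize foreground/background scribbles into labeled pixel sets.

    Lines are traced with Bresenham's algorithm and, for ``width > 1``,
    thickened by dilation with a disk of radius ``(width - 1) // 2``.  Pixels
    claimed by both classes are dropped from both and counted.
    """
    fg_lines = annotations.by_label("foreground")
    bg_lines = annotations.by_label("background")
    if not fg_lines or not bg_lines:
        raise ValueError(
            "annotation must contain at least one foreground and one "
            "background polyline"
        )
    shape = (annotations.height, annotations.width)
    fg = _rasterize_polylines(fg_lines, shape, width)
    bg = _rasterize_polylines(bg_lines, shape, width)
    conflict = fg & bg
    n_conflicts = int(conflict.sum())
    fg &= ~conflict
    bg &= ~conflict
    if not fg.any() or not bg.any():
        raise ValueError("empty class after conflict removal")
    return ScribbleSamples(
        foreground=np.argwhere(fg),
        background=np.argwhere(bg),
        n_conflicts=n_conflicts,
    )


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

MIN_SAMPLES_PER_CLASS = 10
MAX_CLASS_IMBALANCE = 10_000


@dataclass
class PixelClassifierModel:
    """A trained pixel classifier: forest + feature config + provenance."""

    forest: RandomForestClassifier
    feature_config: FeatureConfig
    metadata: dict = field(default_factory=dict)


def _scribble_fingerprint(sample_rows: list[tuple[int, int, int, int]]) -> str:
    h = hashlib.sha1()
    for row in sorted(sample_rows):
        h.update(np.array(row, dtype=np.int64).tobytes())
    return h.hexdigest()


def train_classifier(
    training_data: Sequence[tuple[IntensityImage, AnnotationSet]],
    feature_config: FeatureConfig = FeatureConfig(),
    n_trees: int = 100,
    seed: int = 0,
    scribble_width: int = 1,
    strategy_tag: str | None = None,
    image_ids: Sequence[str] | None = None,
) -> PixelClassifierModel:
    """Train a random forest from scribbles on one or more images.

    Samples from all images are pooled.  Requires at least
    ``MIN_SAMPLES_PER_CLASS`` labeled pixels per class in total and a class
    imbalance no worse than ``MAX_CLASS_IMBALANCE``:1.  The forest uses
    sqrt(n_features) candidate features per split and is fully reproducible
    given the seed.
    """
    if not training_data:
        raise ValueError("training_data must not be empty")
    xs, ys, rows = [], [], []
    n_conflicts = 0
    feature_names: tuple[str, ...] = ()
    for idx, (image, annotations) in enumerate(training_data):
        if image.shape != (annotations.height, annotations.width):
            raise ValueError(
                f"annotation dims {annotations.width}x{annotations.height} do "
                f"not match image shape {image.shape}"
            )
        stack = compute_feature_stack(image, feature_config)
        feature_names = stack.names
        samples = rasterize_scribbles(annotations, width=scribble_width)
        n_conflicts += samples.n_conflicts
        for label, pix in ((1, samples.foreground), (0, samples.background)):
            xs.append(stack.values[pix[:, 0], pix[:, 1], :])
            ys.append(np.full(len(pix), label, dtype=np.int8))
            rows.extend((idx, int(r), int(c), label) for r, c in pix)
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    n_fg = int((y == 1).sum())
    n_bg = int((y == 0).sum())
    if min(n_fg, n_bg) < MIN_SAMPLES_PER_CLASS:
        raise ValueError(
            f"need at least {MIN_SAMPLES_PER_CLASS} samples per class, got "
            f"{n_fg} foreground / {n_bg} background"
        )
    if max(n_fg, n_bg) / min(n_fg, n_bg) > MAX_CLASS_IMBALANCE:
        raise ValueError(
            f"class imbalance {max(n_fg, n_bg)}:{min(n_fg, n_bg)} exceeds "
            f"{MAX_CLASS_IMBALANCE}:1"
        )
    forest = RandomForestClassifier(
        n_estimators=int(n_trees),
        max_features="sqrt",
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)
    metadata = {
        "seed": int(seed),
        "n_trees": int(n_trees),
        "n_foreground": n_fg,
        "n_background": n_bg,
        "n_conflicts": n_conflicts,
        "scribble_fingerprint": _scribble_fingerprint(rows),
        "image_ids": list(image_ids) if image_ids is not None else None,
        "strategy_tag": strategy_tag,
        "feature_names": list(feature_names),
    }
    return PixelClassifierModel(forest=forest, feature_config=feature_config, metadata=metadata)


def predict_mask(
    model: PixelClassifierModel,
    image: IntensityImage,
    prob_threshold: float = 0.5,
) -> SegmentationMask:
    """Predict a binary mask: foreground where P(foreground) >= threshold."""
    stack = compute_feature_stack(image, model.feature_config)
    X = stack.values.reshape(-1, stack.n_features)
    classes = list(model.forest.classes_)
    proba = model.forest.predict_proba(X)[:, classes.index(1)]
    mask = (proba >= prob_threshold).reshape(image.shape)
    return SegmentationMask(mask, connectivity=8)


def save_model(model: PixelClassifierModel, path: str | Path) -> None:
    """Save a model as a single-file archive (metadata + serialized trees)."""
    payload = {
        "format": MODEL_FORMAT,
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_config": {
            "scales": list(model.feature_config.scales),
            "families": list(model.feature_config.families),
        },
        "metadata": model.metadata,
        "forest": model.forest,
    }
    joblib.dump(payload, Path(path))


def load_model(path: str | Path) -> PixelClassifierModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such model file: {path}")
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path} is not a gliaquant model archive")
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version mismatch: file has {version!r}, "
            f"expected {MODEL_SCHEMA_VERSION}"
        )
    cfg = payload["feature_config"]
    return PixelClassifierModel(
        forest=payload["forest"],
        feature_config=FeatureConfig(
            scales=tuple(cfg["scales"]), families=tuple(cfg["families"])
        ),
        metadata=dict(payload["metadata"]),
    )
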