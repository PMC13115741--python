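import numpy as np
import pytest

from gliaquant.imaging_io import (
    AnnotationSet,
    IntensityImage,
    Polyline,
    SegmentationMask,
)
from gliaquant.pixel_classifier import train_classifier
from gliaquant.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def separable_scene():
    """Noiseless two-intensity scene (fg 200 left of x=32, bg 20) with
    one foreground and one background scribble running alongside the
    boundary, and the ground-truth mask."""
    img = np.full((64, 64), 20.0)
    img[:, :32] = 200.0
    image = IntensityImage(img, 0.3)
    annotations = AnnotationSet(
        64,
        64,
        (
            Polyline("foreground", [[2, 32], [30, 32]]),
            Polyline("background", [[33, 32], [61, 32]]),
        ),
    )
    ground_truth = SegmentationMask(img == 200.0)
    return image, annotations, ground_truth


@pytest.fixture(scope="session")
def separable_model(separable_scene):
    image, annotations, _ = separable_scene
    return train_classifier([(image, annotations)])


@pytest.fixture(scope="session")
def small_cohort():
    """A small 2-animal synthetic cohort shared across tests."""
    return generate_cohort(
        CohortConfig(seed=7, n_animals=2, cells_per_condition=3)
    )
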