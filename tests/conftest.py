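"""Shared fixtures: one mid-sized synthetic slide reused across modules."""

import numpy as np
import pytest

from cortexmap.stains import (
    ClassifierParams,
    StainReference,
    classify_pixels,
    segment_nuclei,
    segment_particles,
    tissue_mask,
)
from cortexmap.synthetic import (
    DEFAULT_HEMATOXYLIN_RGB,
    DEFAULT_IMMUNOSTAIN_RGB,
    SlideSpec,
    generate_slide,
)

SEED = 123


@pytest.fixture(scope="session")
def small_spec() -> SlideSpec:
    return SlideSpec(
        width_px=512,
        height_px=512,
        nucleus_count=120,
        particle_count=30,
        min_gap_px=2.0,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def small_slide(small_spec):
    return generate_slide(small_spec)


@pytest.fixture(scope="session")
def stain_ref() -> StainReference:
    return StainReference(
        immunostain_rgb=DEFAULT_IMMUNOSTAIN_RGB,
        hematoxylin_rgb=DEFAULT_HEMATOXYLIN_RGB,
        source_pixel_count=(10, 10),
    )


@pytest.fixture(scope="session")
def small_analysis(small_slide, stain_ref):
    """Tissue mask, label map and segmented centroids of the shared slide."""
    image, _ = small_slide
    params = ClassifierParams()
    tmask = tissue_mask(image, params)
    labels = classify_pixels(image, stain_ref, params, tissue=tmask)
    nuclei = segment_nuclei(image, stain_ref, params, labels, tmask)
    particles = segment_particles(image, stain_ref, params, labels, tmask)
    return {
        "params": params,
        "tissue": tmask,
        "labels": labels,
        "nuclei": nuclei,
        "particles": particles,
    }
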