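"""Shared fixtures: geometric masks and cached synthetic scenes.

Scene segmentation is the slow part of the suite, so default-config scenes
and their segmentations are session-scoped and computed once.
"""
from __future__ import annotations

import numpy as np
import pytest

from organoidq import (
    PipelineParams,
    SceneConfig,
    generate_scene,
    segment_field,
)


def disc_mask(radius: int, size: int | None = None, center=None) -> np.ndarray:
    size = size or (2 * radius + 12)
    if center is None:
        center = (size // 2, size // 2)
    rr, cc = np.mgrid[:size, :size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def boundary_ring(mask: np.ndarray) -> np.ndarray:
    """One-pixel boundary layer of a filled mask (its outermost pixels)."""
    from scipy import ndimage as ndi

    return mask & ~ndi.binary_erosion(mask)


@pytest.fixture(scope="session")
def default_scene():
    """Default-config scene, seed 1: 6 spheroids, 5 budding, 4 junk."""
    return generate_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def default_segmentation(default_scene):
    stack, _truth = default_scene
    return segment_field(stack, PipelineParams().segmentation)


@pytest.fixture(scope="session")
def two_disc_segmentation():
    """Hand-built segmentation of two separated discs, for correction tests."""
    from organoidq.segmentation import SegmentationResult, _records_from_labels

    labels = np.zeros((120, 200), dtype=np.int32)
    rr, cc = np.mgrid[:120, :200]
    labels[(rr - 60) ** 2 + (cc - 55) ** 2 <= 25**2] = 1
    labels[(rr - 60) ** 2 + (cc - 140) ** 2 <= 20**2] = 2
    seg = SegmentationResult(labels=labels, objects=_records_from_labels(labels))
    for o in seg.objects:
        o.class_label = "spheroid"
        o.class_probs = (0.0, 0.1, 0.9)
    return seg
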