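"""Shared fixtures: small synthetic scenes and digitized shapes."""

from __future__ import annotations

import numpy as np
import pytest

from cortex3d.core import MaskStack
from cortex3d.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene (84×84×48 μm) for segmentation/reconstruction tests."""
    params = SceneParams(window_box=(84.0, 84.0, 48.0), seed=42)
    return generate_scene(params)


@pytest.fixture(scope="session")
def small_scene_cells(small_scene):
    from cortex3d.reconstruct import label_and_filter, measure_cells
    from cortex3d.segmentation import reference_segment

    mask = reference_segment(small_scene.stack)
    labels = label_and_filter(mask)
    return measure_cells(labels)


def digitize_ellipsoid(semi_axes, spacing, pad: float = 2.0) -> MaskStack:
    """Binary voxelization of an axis-aligned ellipsoid (voxel-centre test)."""
    a = max(semi_axes)
    dx, dy, dz = spacing
    half = a + pad
    xs = (np.arange(int(2 * half / dx)) + 0.5) * dx - half
    ys = (np.arange(int(2 * half / dy)) + 0.5) * dy - half
    zs = (np.arange(int(2 * half / dz)) + 0.5) * dz - half
    sa, sb, sc = semi_axes
    mask = ((xs[None, None, :] / sa) ** 2 + (ys[None, :, None] / sb) ** 2
            + (zs[:, None, None] / sc) ** 2) <= 1.0
    return MaskStack(mask.astype(np.uint8), spacing)
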