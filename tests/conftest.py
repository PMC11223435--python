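"""Shared phantom fixtures.

Everything is generated at test time from the parametric phantom module;
module-scoped fixtures keep the voxel pipelines (the slow part) to one run
per geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from airwaygeom import (
    PipelineConfig,
    rasterize_phantom,
)
from airwaygeom.phantom import PhantomTreeSpec, attach, straight
from airwaygeom.pipeline import run_pipeline


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Straight tube r = 3 mm, L = 40 mm at 0.5 mm isotropic spacing."""
    seg = straight("trunk", radius=3.0, length=40.0, start=(0, 0, 0),
                   direction=(0, 0, -1))
    spec = PhantomTreeSpec(segments=[seg], spacing=(0.5, 0.5, 0.5))
    return rasterize_phantom(spec)


@pytest.fixture(scope="session")
def y_phantom():
    """Symmetric Y: trunk r = 3 mm with two 35-degree children, lesion at a leaf."""
    trunk = straight("trunk", 3.0, 30.0, start=(0, 0, 0), direction=(0, 0, -1))
    c1 = attach(trunk, "c1", 2.2, 25.0, angle_deg=35.0, azimuth_deg=0.0)
    c2 = attach(trunk, "c2", 2.2, 25.0, angle_deg=35.0, azimuth_deg=180.0)
    spec = PhantomTreeSpec(segments=[trunk, c1, c2], spacing=(0.5, 0.5, 0.5),
                           lesion_segment="c1")
    return rasterize_phantom(spec)


@pytest.fixture(scope="session")
def y_result(y_phantom):
    _, mask, gt = y_phantom
    return run_pipeline(mask, gt.lesion)


@pytest.fixture(scope="session")
def three_gen_phantom():
    """Three generations with a curved middle section (torus arc)."""
    from airwaygeom.phantom import example_tree

    return rasterize_phantom(example_tree())


@pytest.fixture(scope="session")
def three_gen_result(three_gen_phantom):
    _, mask, gt = three_gen_phantom
    return run_pipeline(mask, gt.lesion)
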