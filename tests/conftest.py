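"""Shared fixtures: desk-scale geometries and simulated stacks.

Synthetic stacks keep the standard axial sampling (many slices at a
2.8 um step) but use reduced lateral fields at 0.75 um/px so the suite
stays fast; area/volume thresholds are in physical units and unaffected.
"""

import numpy as np
import pytest

from nccv import AcquisitionGeometry, SegmentationParams, SimConfig, simulate_stack


@pytest.fixture(scope="session")
def desk_geom() -> AcquisitionGeometry:
    """Full 78-slice acquisition on a reduced 240 um field."""
    return AcquisitionGeometry(
        pixel_size_um=0.75, step_um=2.8, n_slices=78, field_um=240.0
    )


@pytest.fixture(scope="session")
def tiny_geom() -> AcquisitionGeometry:
    """Short stack (24 slices, 60 um field) for fast unit tests."""
    return AcquisitionGeometry(
        pixel_size_um=0.75, step_um=2.8, n_slices=24, field_um=60.0
    )


@pytest.fixture(scope="session")
def desk_config(desk_geom) -> SimConfig:
    """Patient-like desk-scale stack: one papilla, 40 crystals."""
    return SimConfig(geometry=desk_geom, n_crystals=40, n_papillae=1, seed=0)


@pytest.fixture(scope="session")
def desk_stack(desk_config):
    """One simulated stack + ground truth shared across read-only tests."""
    return simulate_stack(desk_config)


@pytest.fixture
def default_params() -> SegmentationParams:
    return SegmentationParams()


def make_flat_stack(geometry: AcquisitionGeometry, value: int = 0):
    """Uniform stack at ``value`` (uint16) with the given geometry."""
    from nccv import ImageStack

    npx = int(round(geometry.field_um / geometry.pixel_size_um))
    voxels = np.full((geometry.n_slices, npx, npx), value, dtype=np.uint16)
    return ImageStack(voxels=voxels, geometry=geometry)


@pytest.fixture
def flat_stack(tiny_geom):
    return make_flat_stack(tiny_geom, 0)
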