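"""Shared fixtures: small synthetic grids and insertion records.

All fixtures are generated programmatically; coarse-pitch grids keep the
volumes small so rendering stays fast while preserving the full field of
view in millimetres.
"""

import numpy as np
import pytest

from needletrack import (
    MediumSpec,
    NeedleSpec,
    TrajectorySpec,
    VolumeGrid,
    generate_dataset,
    simulate_insertion,
)
from needletrack.phantom_sim import DEFAULT_TRANSFORM


@pytest.fixture(scope="session")
def full_grid() -> VolumeGrid:
    """The acquisition-scale lattice: 117 x 134 x 134 at 0.3 mm."""
    return VolumeGrid()


@pytest.fixture(scope="session")
def coarse_grid() -> VolumeGrid:
    """Same FOV at 1.2 mm pitch — small volumes for fast tests."""
    return VolumeGrid.from_fov(pitch=1.2)


@pytest.fixture(scope="session")
def mid_grid() -> VolumeGrid:
    """Same FOV at 0.6 mm pitch."""
    return VolumeGrid.from_fov(pitch=0.6)


@pytest.fixture(scope="session")
def water_insertion_coarse(coarse_grid):
    spec = TrajectorySpec(start_H=(-20.0, 0.0, -13.0))
    return simulate_insertion(
        coarse_grid, MediumSpec.water(), NeedleSpec(), spec, seed=42, insertion_id="w0"
    )


@pytest.fixture(scope="session")
def parallel_records_coarse(coarse_grid):
    """Full parallel protocol at coarse pitch and 1 Hz (11 frames/insertion)."""
    return generate_dataset("parallel", grid=coarse_grid, seed=7, frame_rate=1.0)


@pytest.fixture(scope="session")
def parallel_manifest_coarse(parallel_records_coarse, coarse_grid):
    from needletrack.phantom_sim import dataset_manifest

    return dataset_manifest(parallel_records_coarse, pitch=coarse_grid.pitch)


@pytest.fixture(scope="session")
def rig_transform():
    return DEFAULT_TRANSFORM
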