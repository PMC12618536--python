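"""Shared fixtures: scaled-down instrument geometries and bead scenes.

The test geometry keeps the instrument's dimensionless relationships (NA
window inside the carrier separation, carriers inside Nyquist) at 256x256
or 128x128 pixels so that every pipeline stage runs in seconds.
"""

import numpy as np
import pytest

from bqsm.model import CameraModel, OpticalConfig
from bqsm.particles import ScatterModelGrid
from bqsm.simulator import BeadSpec, SimScene


@pytest.fixture(scope="session")
def cfg256() -> OpticalConfig:
    """256-px sensor; carriers at 0.3125 cycles/px (integer DFT bins) keep the second-order
    object-field halo clear of the AC lobes."""
    return OpticalConfig(
        sensor_shape=(256, 256),
        sensor_pixel_pitch=7000.0,
        aperture_radius_px=28.0,
        carrier_fs=(0.3125, 0.0),
        carrier_bs=(0.0, 0.3125),
    )


@pytest.fixture(scope="session")
def cfg128() -> OpticalConfig:
    return OpticalConfig(
        sensor_shape=(128, 128),
        sensor_pixel_pitch=7000.0,
        aperture_radius_px=14.0,
        carrier_fs=(0.3125, 0.0),
        carrier_bs=(0.0, 0.3125),
    )


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def bead_scene(cfg256) -> SimScene:
    """One 203-nm silica bead at the center, no noise sources."""
    return SimScene(
        beads=[BeadSpec(203.0, 1.43, np.array([[128.0, 128.0, 0.0]]))],
        seed=11,
    )


@pytest.fixture(scope="session")
def model_grid(cfg256) -> ScatterModelGrid:
    """Coarse (n, d) model grid shared by inversion tests; the local
    refinement step makes the coarseness irrelevant to accuracy."""
    return ScatterModelGrid.build(
        cfg256, n_range=(1.34, 1.70), n_step=0.004, d_range=(20.0, 1000.0), d_step=5.0
    )
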