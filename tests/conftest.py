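import datetime as dt

import numpy as np
import pytest

from lakebloom.detection import (
    BANDS_NM,
    DetectionParams,
    LakeGeometry,
    Scene,
)
from lakebloom.synthetic import (
    BLOOM_SPECTRUM,
    CLOUD_SPECTRUM,
    WATER_SPECTRUM,
    SimulationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_lakes=4, year_start=2003, year_end=2004, grid_size=16, seed=11
    )


@pytest.fixture
def simple_geometry():
    """16x16 all-water lake, fringe water-presence 0.3, 1 km2 pixels."""
    n = 16
    wp = np.full((n, n), 0.95)
    wp[:2, :] = wp[-2:, :] = wp[:, :2] = wp[:, -2:] = 0.30
    return LakeGeometry(
        lake_id="fixture",
        lake_mask=np.ones((n, n), dtype=bool),
        area_km2=float(n * n),
        water_presence=wp,
    )


def make_scene(
    bloom_pixels=(), cloud_pixels=(), n=16, date=dt.date(2010, 7, 15)
) -> Scene:
    """Build a noise-free scene from the reference spectra.

    ``bloom_pixels`` / ``cloud_pixels`` are iterables of (y, x); cloud wins
    where they overlap and is marked invalid.
    """
    refl = np.empty((len(BANDS_NM), n, n))
    refl[:] = WATER_SPECTRUM[:, None, None]
    valid = np.ones((n, n), dtype=bool)
    for y, x in bloom_pixels:
        refl[:, y, x] = BLOOM_SPECTRUM
    for y, x in cloud_pixels:
        refl[:, y, x] = CLOUD_SPECTRUM
        valid[y, x] = False
    return Scene(date=date, reflectance=refl, valid_mask=valid)


@pytest.fixture
def default_params():
    return DetectionParams()
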