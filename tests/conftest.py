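import numpy as np
import pytest

from crowdprf.hemodynamics import HRFSpec
from crowdprf.prf import GridPredictions, default_coarse_grid
from crowdprf.stimulus import FieldRaster, bar_aperture_run


@pytest.fixture(scope="session")
def small_raster():
    """Coarse 41x41 raster over +/-9 deg (fast; ~0.45 deg pixels)."""
    return FieldRaster(half_width=9.0, n_pixels=41)


@pytest.fixture(scope="session")
def hrf():
    return HRFSpec()


@pytest.fixture(scope="session")
def bar_movie(small_raster):
    """One 8-direction bar run, 16 steps of 2 s per sweep (256 s, 128 TRs)."""
    return bar_aperture_run(small_raster, n_steps=16, step_duration=2.0, tr=2.0)


@pytest.fixture(scope="session")
def coarse_grid_predictions(bar_movie, hrf):
    """Default coarse grid precomputed once for the whole session."""
    return GridPredictions(bar_movie, hrf, default_coarse_grid(9.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
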