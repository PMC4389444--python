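import numpy as np
import pytest

from spatrisk.grids import RasterGrid, Window
from spatrisk.patterns import PointPattern
from spatrisk.synthetic import RegionConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study region for fast unit tests."""
    return RegionConfig(
        window_size=10_000.0,
        pop_cell_size=40.0,
        analysis_cell_size=200.0,
        n_communities=3,
        n_tracts=3,
        n_cores=2,
        total_population=60_000.0,
        n_cases=400,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """One realisation of the full default study region."""
    return generate_study(seed=11)


@pytest.fixture
def unit_window():
    return Window(0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def coarse_grid(unit_window):
    return RasterGrid.full(unit_window, 50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_pattern(n, window, rng, scale_frac=0.15):
    """Points from a bivariate normal centred in the window, clipped inside."""
    centre = np.array([(window.xmin + window.xmax) / 2,
                       (window.ymin + window.ymax) / 2])
    sd = scale_frac * min(window.width, window.height)
    pts = rng.normal(centre, sd, size=(n, 2))
    pts[:, 0] = np.clip(pts[:, 0], window.xmin, window.xmax)
    pts[:, 1] = np.clip(pts[:, 1], window.ymin, window.ymax)
    return PointPattern(pts, window)
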