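import numpy as np
import pytest
from shapely.geometry import box

from invasionkit import (
    OccurrenceSeries,
    SpatialWindow,
    SuitabilityRaster,
    VirtualInvasionParams,
    coastline_window,
    generate_virtual_invasion,
)


@pytest.fixture(scope="session")
def unit_square_window():
    return SpatialWindow(box(0.0, 0.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def big_square_window():
    return SpatialWindow(box(0.0, 0.0, 1000.0, 1000.0))


@pytest.fixture(scope="session")
def coastline():
    return coastline_window()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_invasion(coastline):
    """A labelled virtual invasion small enough for fast tests."""
    params = VirtualInvasionParams(
        alpha=15.0, n_total=150, anthro_frac=0.1, n_years=40, window=coastline
    )
    return generate_virtual_invasion(params, np.random.default_rng(42))


def make_series(points, years, window, origin=None):
    import pandas as pd

    frame = pd.DataFrame(
        {"x": [p[0] for p in points], "y": [p[1] for p in points], "year": years}
    )
    if origin is not None:
        frame["origin"] = origin
    return OccurrenceSeries(frame, window, validate=False)


@pytest.fixture(scope="session")
def two_cell_raster():
    """1x2 raster: left cell 0.2, right cell 0.8, cells of side 1."""
    return SuitabilityRaster(values=np.array([[0.2, 0.8]]), xll=0.0, yll=0.0,
                             cell_size=1.0)
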