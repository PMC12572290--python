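import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from ldis import PipelineConfig
from ldis._geodesy import LocalMetricFrame
from ldis.raster import Raster


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def frame() -> LocalMetricFrame:
    """Local metric frame near the equator used to build metric fixtures."""
    return LocalMetricFrame(36.8, -1.3)


@pytest.fixture
def metric_polygon(frame):
    """Build a WGS84 polygon from metre coordinates around the frame centre."""

    def build(coords_m):
        return frame.to_wgs84(Polygon(coords_m))

    return build


@pytest.fixture
def unit_square_km(metric_polygon):
    """1 km x 1 km square centred on the frame origin."""
    return metric_polygon([(-500, -500), (500, -500), (500, 500), (-500, 500)])


def make_raster(values, frame, cell_m=10.0, origin_m=(-1000.0, 1000.0)) -> Raster:
    """Raster whose top-left corner sits at ``origin_m`` in the metric frame."""
    deg = cell_m / 111_132.954
    lon0, lat0 = frame.inverse_lonlat(np.array(origin_m[0]), np.array(origin_m[1]))
    return Raster(np.asarray(values), x0=float(lon0), y0=float(lat0), dx=deg, dy=deg)


@pytest.fixture
def raster_factory(frame):
    def build(values, cell_m=10.0, origin_m=(-1000.0, 1000.0)):
        return make_raster(values, frame, cell_m, origin_m)

    return build


@pytest.fixture
def site_table(unit_square_km):
    """Minimal harmonised single-site table with derived geometry filled."""
    from ldis.sites_io import derive_geometry, harmonize_sites

    df = pd.DataFrame({
        "site_id": ["a"],
        "geometry_reported": [unit_square_km],
        "planting_date_reported": ["2018"],
    })
    return derive_geometry(harmonize_sites(df))
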