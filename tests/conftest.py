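import numpy as np
import pytest
from shapely.geometry import Polygon, box

import boreal
from boreal.grids import RangePolygon, RasterGrid


@pytest.fixture
def unit_grid():
    """20x20 boolean grid of 1 m cells with origin at (0, 20)."""
    return RasterGrid(np.zeros((20, 20), dtype=bool), resolution=1.0, origin=(0.0, 20.0))


@pytest.fixture
def square_range():
    """Square range exactly covering the 20x20 unit grid."""
    return RangePolygon(box(0, 0, 20, 20), name="square")


@pytest.fixture(scope="session")
def small_landscape():
    """20 km x 20 km landscape at 250 m cells, seeded; shared read-only."""
    spec = boreal.LandscapeSpec(extent_km=(20.0, 20.0), resolution_m=250.0, seed=11)
    return boreal.generate_landscape(spec)


@pytest.fixture(scope="session")
def nested_scenarios(small_landscape):
    """Scenario feature sets calibrated to the three study disturbance levels."""
    specs, feature_sets = boreal.calibrate_scenarios(
        small_landscape, target_pct_anthro=[0.41, 1.11, 16.91], seed=7
    )
    return specs, feature_sets


@pytest.fixture(scope="session")
def default_model():
    from boreal.demography import default_model

    return default_model()
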