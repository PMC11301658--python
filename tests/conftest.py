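import numpy as np
import pandas as pd
import pytest

from scalesdm.raster import RasterField


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160601)


@pytest.fixture(scope="session")
def half_normal_distances():
    """5,000 half-normal perpendicular distances, sigma=200 m, w=500 m."""
    r = np.random.default_rng(7)
    x = np.abs(r.normal(0.0, 200.0, size=40_000))
    x = x[x <= 500.0]
    return x[:5000]


@pytest.fixture(scope="session")
def small_cell_world():
    """Cell-year rows from a small synthetic world with a 40 km/monthly truth."""
    from scalesdm.synth import TruthSpec, simulate_cell_rows

    return simulate_cell_rows(TruthSpec(), seed=11, add_noise_covariate=True)


def make_field(values, cell_km=5.0, origin=(0.0, 0.0), name="sst", time="2016-06-01"):
    return RasterField(values=np.asarray(values, float), origin=origin,
                       cell_km=cell_km, name=name, time=time)


@pytest.fixture
def field_factory():
    return make_field


@pytest.fixture(scope="session")
def presence_frame():
    """Deterministic 400-row frame: 100 presences, a noise covariate."""
    r = np.random.default_rng(3)
    y = np.zeros(400)
    y[:100] = 1.0
    return pd.DataFrame({"presence": y, "x": r.normal(size=400)})
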