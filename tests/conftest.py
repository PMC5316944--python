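import numpy as np
import pandas as pd
import pytest

from seatrack import (FilterConfig, SimConfig, TagDeployment, build_grid,
                      make_environment)


@pytest.fixture(scope="session")
def env():
    """One shared synthetic environment (default NE-Atlantic-like domain)."""
    return make_environment(seed=11, n_days=366)


@pytest.fixture(scope="session")
def deployment():
    return TagDeployment("tag001", "2014-07-01", -9.0, 56.0)


@pytest.fixture
def sim_config():
    return SimConfig(seed=4)


@pytest.fixture
def filter_config():
    return FilterConfig()


def flat_sea_grid(extent, resolution, depth=4000.0):
    """All-sea grid of constant depth (helper, not a fixture)."""
    lon_min, lon_max, lat_min, lat_max = extent
    lons = np.linspace(lon_min, lon_max, 30)
    lats = np.linspace(lat_min, lat_max, 30)
    bathy = np.full((30, 30), depth)
    return build_grid(extent, resolution, (lons, lats, bathy))


@pytest.fixture
def toy_argos():
    """Hand-built Argos fix table with known classes and times."""
    ts = pd.to_datetime([
        "2014-07-01 09:00", "2014-07-01 13:00",
        "2014-07-02 06:00", "2014-07-02 18:00", "2014-07-02 20:00",
        "2014-07-03 12:00",
    ])
    return pd.DataFrame({
        "timestamp": ts,
        "lon": [-9.0, -9.01, -9.02, -9.03, -9.04, -9.05],
        "lat": [56.0, 56.01, 56.02, 56.03, 56.04, 56.05],
        "loc_class": ["2", "2", "B", "2", "A", "3"],
    })
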