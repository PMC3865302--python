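import numpy as np
import pandas as pd
import pytest

from firegwr.grid_data import build_dataset, cell_area
from firegwr.synthetic import SyntheticScenario, simulate_gwr_world


def make_raw(lon, lat, burned, pop, combustible=None, anthrome="Rangelands",
             continent="Africa", resolution=1.0):
    """Hand-built raw cell table with consistent areas."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    return pd.DataFrame({
        "lon": lon,
        "lat": lat,
        "burned_area": np.asarray(burned, dtype=float),
        "pop_density": np.asarray(pop, dtype=float),
        "combustible": np.ones(n, dtype=bool) if combustible is None else np.asarray(combustible),
        "anthrome": [anthrome] * n if isinstance(anthrome, str) else list(anthrome),
        "continent": [continent] * n if isinstance(continent, str) else list(continent),
        "cell_area": cell_area(lat, resolution),
    })


@pytest.fixture(scope="session")
def small_world():
    """15x15 zero-noise nonstationary world with stored truth."""
    sc = SyntheticScenario(n_lon=15, n_lat=15, noise_sd=0.0, mask_fraction=0.0, seed=42)
    return simulate_gwr_world(sc)


@pytest.fixture(scope="session")
def noisy_world():
    """20x20 default-noise nonstationary world."""
    sc = SyntheticScenario(n_lon=20, n_lat=20, seed=7)
    return simulate_gwr_world(sc)
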