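import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from geobaci.grid import Affine, GridGeometry


@pytest.fixture
def grid10():
    """10x10 grid, 60 m cells, origin (0, 600), UTM 35S."""
    return GridGeometry(10, 10, Affine.north_up(0.0, 600.0, 60.0), "EPSG:32735")


@pytest.fixture
def square_300():
    """A 300 m square intervention polygon at the origin."""
    return box(0.0, 0.0, 300.0, 300.0)


def make_table(n_impact, n_control, covs, seed=0, categorical=()):
    """Unit table with named covariate generators (callables or arrays)."""
    rng = np.random.default_rng(seed)
    n = n_impact + n_control
    df = pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "treatment": np.r_[np.ones(n_impact, int), np.zeros(n_control, int)],
        }
    )
    for name, gen in covs.items():
        df[name] = gen(rng, n) if callable(gen) else np.asarray(gen)
    df.attrs["categorical"] = list(categorical)
    return df


@pytest.fixture
def table_factory():
    return make_table
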