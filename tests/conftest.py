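import numpy as np
import pandas as pd
import pytest

from routesdm.grid import GridSpec
from routesdm.world import default_world, make_routes, make_species, make_world


@pytest.fixture(scope="session")
def small_env():
    return make_world(seed=11, n_rows=20, n_cols=24, n_layers=4)


@pytest.fixture(scope="session")
def small_truth(small_env):
    return make_species(small_env, seed=12, n_species=12, class_sizes=(6, 4, 2),
                        class_labels=("teleost", "elasmobranch", "mammal"))


@pytest.fixture(scope="session")
def small_net(small_env):
    return make_routes(small_env, seed=13, n_routes=6)


@pytest.fixture(scope="session")
def default_trio():
    """The default study conditions: env, truth community, route network."""
    return default_world(1)


@pytest.fixture
def line_grid():
    """1x3 all-sea grid for hand-computed map examples."""
    return GridSpec(1, 3, 0.0, 0.0, 1.0, np.ones((1, 3), dtype=bool))


@pytest.fixture(scope="session")
def make_census():
    """Factory: occurrence table containing every presence of every species."""

    def _make(truth):
        sea_r, sea_c = truth.grid.sea_indices()
        lon, lat = truth.grid.sea_cell_centers()
        names = np.array(truth.names, dtype=object)
        parts = []
        for s in range(truth.n_species):
            occ = truth.occupancy[s, sea_r, sea_c]
            parts.append(pd.DataFrame({"species": names[s], "lon": lon[occ],
                                       "lat": lat[occ], "year": 2020,
                                       "month": 1}))
        return pd.concat(parts, ignore_index=True)

    return _make
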