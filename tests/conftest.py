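import numpy as np
import pandas as pd
import pytest

from domseason.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(config):
    """One full synthetic study shared across tests (seed fixed)."""
    return generate_dataset(config)


@pytest.fixture(scope="session")
def grid_mld(config):
    """MLD series snapped to depth-grid nodes, for exact-conservation work."""
    from domseason.synthetic import simulate_seasonal_mld

    mld = simulate_seasonal_mld(config)
    z = config.depth_grid
    snapped = z[np.abs(z[:, None] - mld.to_numpy()[None, :]).argmin(axis=0)]
    return pd.Series(snapped, index=mld.index)
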