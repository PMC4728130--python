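import numpy as np
import pytest

from heartclones.geometry import make_half_heart_slab
from heartclones.simulator import RegionSim, SimulationConfig


@pytest.fixture(scope="session")
def default_geometry():
    return make_half_heart_slab()


@pytest.fixture
def small_config(default_geometry):
    """Paper geometry, modest replicate count for cheap tests."""
    return SimulationConfig(
        geometry=default_geometry, rate_m=3.9, n_sims=500, seed=11
    )


def region_from_labels(labels):
    """Build a RegionSim with the given cluster labels and dummy,
    well-separated positions (for statistics-only tests)."""
    labels = np.asarray(labels, dtype=np.intp)
    k = len(labels)
    pts = np.column_stack(
        [np.arange(k) * 1e4, np.zeros(k), np.zeros(k)]
    ).astype(float)
    return RegionSim(clones=pts, labels=labels)
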