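import numpy as np
import pytest

from ecoevosim.landscape import ConnectionCostMatrix
from ecoevosim.species import SpeciesState
from ecoevosim.worlds import WorldSpec, barrier_toy, latitudinal_world


@pytest.fixture(scope="session")
def barrier_world():
    return barrier_toy()


@pytest.fixture(scope="session")
def small_world():
    """A quick 10×8 latitudinal world (10 steps) for engine unit tests."""
    return latitudinal_world(
        WorldSpec(n_lon=10, n_lat=8, resolution_deg=5.0, n_steps=10, ocean_columns=(4,))
    )


@pytest.fixture(scope="session")
def default_world():
    return latitudinal_world()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_cost_matrix(site_ids, dense):
    """Wrap a dense symmetric cost array as a ConnectionCostMatrix."""
    dense = np.asarray(dense, dtype=float)
    np.fill_diagonal(dense, 0.0)
    return ConnectionCostMatrix(np.asarray(site_ids, dtype=int), dense)


def make_species(site_ids, abundance=None, t_opt=None, divergence=None, species_id=0):
    site_ids = np.asarray(site_ids, dtype=int)
    n = site_ids.size
    return SpeciesState(
        species_id=species_id,
        site_ids=site_ids,
        abundance=np.full(n, 10) if abundance is None else np.asarray(abundance),
        traits={"t_opt": np.full(n, 0.5) if t_opt is None else np.asarray(t_opt, float)},
        divergence=divergence,
    )
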