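import numpy as np
import pytest

from fwalign.alignment import AlignConfig
from fwalign.motifs import build_motif_catalog
from fwalign.synthgen import NicheParams, niche_web
from fwalign.webio import FoodWeb


@pytest.fixture(scope="session")
def catalog():
    return build_motif_catalog(max_n=3)


@pytest.fixture
def chain_web():
    """a -> b -> c."""
    return FoodWeb("chain", ["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def star_web():
    """One resource eaten by three consumers."""
    return FoodWeb("star", ["hub", "x", "y", "z"],
                   [("hub", "x"), ("hub", "y"), ("hub", "z")])


@pytest.fixture
def niche_factory():
    def make(n, C=0.15, seed=0, web_id=None):
        return niche_web(NicheParams(n, C, seed), web_id=web_id)
    return make


@pytest.fixture
def fast_config():
    """Annealing schedule sized for small test problems."""
    return AlignConfig(seed=1, restarts=2, sweep_length=300,
                       max_stale_stages=10)
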