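import numpy as np
import pytest

from geoadditive import default_truth, simulate_dataset
from geoadditive.mcmc import MCMCConfig, run_chain
from geoadditive.models import build_model


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured synthetic survey (3x3 lattice, n=1200)."""
    truth = default_truth(n=1200, rows=3, cols=3)
    return simulate_dataset(truth, seed=42)


@pytest.fixture(scope="session")
def m5_chain(small_sim):
    """A short M5 chain on the small survey, shared across reporting tests."""
    truth = small_sim.truth
    model = build_model(
        "M5", small_sim.dataset, "hypertension", list(truth.fixed_effects),
        graph=small_sim.graph, n_interior_knots=10,
    )
    return run_chain(model, MCMCConfig(iterations=800, burn_in=200, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
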