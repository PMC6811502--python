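"""Shared fixtures: small networks and cached simulated responses.

Everything is generated programmatically from fixed seeds; the expensive
simulate-and-reconstruct artifacts are session-scoped so several tests can
share one run.
"""

import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from balnet import (
    NetworkParams,
    generate_connectivity,
    generate_input_ensemble,
    run_ensemble,
)

# silence the deliberate small-penalty coordinate-descent convergence chatter
warnings.filterwarnings("ignore", message="Objective did not converge")


@pytest.fixture(scope="session")
def default_params():
    return NetworkParams()


@pytest.fixture(scope="session")
def small_params():
    """A small balanced network in the compressive regime (r < N)."""
    return NetworkParams(N_E=160, N_I=40, K=8)


@pytest.fixture(scope="session")
def small_network(small_params):
    return generate_connectivity(small_params, seed=42)


@pytest.fixture(scope="session")
def small_response(small_params, small_network):
    """150 trials of 1.5 s on the small balanced network (r=150 < N=200)."""
    ensemble = generate_input_ensemble(small_params, r=150, seed=42)
    response = run_ensemble(
        small_network, ensemble, t_obs=1500.0, t_burn=500.0, seed=42, track_ei=True
    )
    return ensemble, response


@pytest.fixture
def rng():
    return np.random.default_rng(7)
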