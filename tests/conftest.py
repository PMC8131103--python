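import numpy as np
import pytest

from adhesim.cytoneme_sim import CytonemeParams, CytonemeState


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def base_params():
    """Small, fast cytoneme schedule with the standard rate constants."""
    return CytonemeParams(
        surface_length=20,
        occupancy_fraction=0.3,
        total_steps=2_000,
        burn_in_steps=500,
        snapshot_interval=10,
        snapshot_count=100,
        seed=7,
    )


def make_state(positions, lengths, surface_length):
    return CytonemeState(
        positions=np.asarray(positions),
        lengths=np.asarray(lengths),
        surface_length=surface_length,
    )


@pytest.fixture
def pair_state():
    """Two adjacent cytonemes of lengths 4 and 6 on a 10-site surface."""
    return make_state([2, 3], [4, 6], 10)
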