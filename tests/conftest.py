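import numpy as np
import pytest

from alpgraze.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study: 3 cows per breed, ~7 h of tracking per
    pasture, 150 bites per cow and pasture.  Session-scoped: several test
    modules share it read-only."""
    cfg = SimConfig(
        n_cows_per_breed=3,
        track_days_per_pasture=0.3,
        n_bites_per_pasture=150,
    )
    return simulate_study(cfg, seed=20240917)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
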