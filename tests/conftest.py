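import numpy as np
import pytest

from mxstrat import get_detector, get_goniostat, merge_stats, simulate_sweeps


@pytest.fixture(scope="session")
def mini_kappa():
    return get_goniostat("mini-kappa")


@pytest.fixture(scope="session")
def pilatus6m():
    return get_detector("pilatus6m")


@pytest.fixture(scope="session")
def sim_stats():
    """Simulate sweeps and merge in one call (no detector unless given)."""

    def run(crystal, sweeps, d_min, detector=None, distance=None, friedel=True,
            **sim_kw):
        obs = simulate_sweeps(crystal, sweeps, detector, distance, d_min=d_min,
                              **sim_kw)
        pg = crystal.strategy_class().point_group
        return merge_stats(obs, pg, friedel=friedel, crystal=crystal,
                           sweeps=sweeps, d_min=d_min)

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
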