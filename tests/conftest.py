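import numpy as np
import pytest

from fstprior import SimConfig, run_simulation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A minutes-scale configuration exercising every pipeline stage."""
    return SimConfig.desk_scale(
        seed=7,
        n_markers=600,
        n_qtl=20,
        n_hist_generations=40,
        hist_size=120,
        n_expand_generations=3,
        expand_size_start=300,
        expand_size_end=600,
        n_founder_males=50,
        n_founder_females=500,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return run_simulation(tiny_config)
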