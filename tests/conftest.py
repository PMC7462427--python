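import numpy as np
import pytest

from netreconf import BandPlan, SimulationConfig, WindowSpec


@pytest.fixture
def two_node_coupled_cfg():
    """Two nodes, one community, quarter-cycle relative lag at 10 Hz."""
    plan = BandPlan(
        band=(8.0, 12.0),
        pre_partition=(1, 1),
        post_partition=(1, 1),
        coupling=1.0,
        lag_cycles=(0.0, 0.25),
    )
    return SimulationConfig(
        n_regions=2,
        fs=128.0,
        epoch_span=(-1.5, 1.5),
        n_trials=200,
        bands=(plan,),
        noise_sd=0.05,
        seed=7,
        n_subjects=1,
    )


@pytest.fixture
def short_window_spec():
    return WindowSpec(epoch_span=(-1.5, 1.5))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
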