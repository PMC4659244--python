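import numpy as np
import pytest

from latentgrn.network import TransitionNetwork, all_configs, make_biased_cpt
from latentgrn.synthetic import GenConfig, gen_case1_network, simulate_series
from latentgrn.timeseries import TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def case1_net(rng):
    """One hidden node (id 3) with 3 observed children, p_bias 0.75."""
    cfg = GenConfig(case="I", p=0, c=3, p_bias=0.75)
    return gen_case1_network(cfg, rng)


@pytest.fixture
def single_edge_net(rng):
    """a(0) -> b(1) with delay 2 and strong bias, for simulation tests."""
    net = TransitionNetwork(n_obs=2, n_states=3, max_delay=4)
    net.add_edge(0, 1, 2)
    net.cpts[0] = make_biased_cpt(3, 0.85, [()], rng, parent_list=[])
    net.cpts[1] = make_biased_cpt(3, 0.85, all_configs(3, 1), rng, parent_list=[(0, 2)])
    return net


@pytest.fixture
def single_edge_data(single_edge_net, rng):
    mat = simulate_series(single_edge_net, 800, rng)
    return TimeSeriesSet([mat], n_states=3)
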