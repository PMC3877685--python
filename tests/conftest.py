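import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cossy.network_io import InteractionNetwork
from cossy.synthetic import SyntheticSpec, make_expression, make_network

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def simple_network(edges, molecules=None):
    """Network with one molecule g<node> per node unless a map is given."""
    nodes = {n for e in edges for n in e}
    if molecules is None:
        molecules = {n: {f"g{n}"} for n in nodes}
    return InteractionNetwork(edges, molecules)


@pytest.fixture
def strong_signal_data():
    """5 planted communities, one carrying a 5-sigma mixed-sign signal, M=20."""
    spec = SyntheticSpec(
        n_communities=5,
        community_size=10,
        effect_size=5.0,
        M_pos=10,
        M_neg=10,
        probes_per_molecule=2,
        seed=11,
    )
    network, truth = make_network(spec)
    dataset = make_expression(spec, truth)
    return spec, network, truth, dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
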