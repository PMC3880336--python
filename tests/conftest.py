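"""Shared fixtures.

The expensive trained networks are session-scoped: the adjusted-network
build is cheap, but association training and the 300-recall consolidation
run are reused by several tests.
"""

import numpy as np
import pytest

import cortohipp as ch
from cortohipp.circuit import Network, SynapseTable
from cortohipp.dynamics import EXCITATORY, NeuronPopulationState
from cortohipp.protocols import DISPERSION_FORWARD_WEIGHT


@pytest.fixture(scope="session")
def adjusted_net():
    """The adjusted h=100, c=300, d=50 network (untrained)."""
    return ch.make_network(ch.LoopConfig(h=100, c=300, d=50), seed=3)


@pytest.fixture(scope="session")
def dispersion_cfg():
    return ch.LoopConfig(
        h=100, c=300, d=None, dispersion=True,
        forward_weight_mean=DISPERSION_FORWARD_WEIGHT,
    )


@pytest.fixture(scope="session")
def trained_d50():
    """d=50 network after 60 A->B training trials at 120 ms separation."""
    net = ch.make_network(ch.LoopConfig(h=100, c=300, d=50), seed=3)
    ch.train_association(
        net, ch.TrainingSchedule(ch.PATTERN_A, ch.PATTERN_B, 120.0, trials=60), seed=11
    )
    return net


@pytest.fixture(scope="session")
def consolidated_dispersion(dispersion_cfg):
    """Dispersion network trained at 120 ms, then consolidated over 300
    plasticity-on recalls; returns (network, consolidation curve)."""
    net = ch.make_network(dispersion_cfg, seed=3)
    ch.train_association(
        net, ch.TrainingSchedule(ch.PATTERN_A, ch.PATTERN_B, 120.0, trials=60), seed=11
    )
    curve = ch.consolidate(
        net, ch.PATTERN_A, ch.PATTERN_B, n_recalls=300, probe_every=100, seed=13
    )
    return net, curve


def micro_network(n, synapses, plasticity=None):
    """Hand-built network: ``synapses`` is a list of
    (pre, post, weight, delay, plastic, cap)."""
    state = NeuronPopulationState([EXCITATORY] * n)
    if synapses:
        pre, post, w, d, pl, cap = map(np.asarray, zip(*synapses))
    else:
        pre = post = np.empty(0, int)
        w = cap = np.empty(0, float)
        d = np.empty(0, int)
        pl = np.empty(0, bool)
    syn = SynapseTable(
        pre=pre.astype(np.int32),
        post=post.astype(np.int32),
        weight=w.astype(float),
        delay=d.astype(np.int16),
        plastic=pl.astype(bool),
        cls=np.zeros(len(pre), dtype=np.int8),
        cap=cap.astype(float),
    )
    net = Network(state, syn, cfg=None, plasticity=plasticity)
    return net


@pytest.fixture
def micro_net_factory():
    return micro_network
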