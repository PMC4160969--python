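import numpy as np
import pytest

from stdpsim.connectivity import SparseWeightMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_synapse():
    """1x1 weight matrix at w=10 in float64 (plasticity micro-tests)."""
    return SparseWeightMatrix.from_coo(1, 1, [0], [0], [10.0], dtype=np.float64)


def step_rule(rule, pre_arrival_steps, post_steps, n_steps, dt=0.1, flush=False):
    """Drive a plasticity rule exactly like the engine does.

    ``pre_arrival_steps`` are the steps at which the (delayed) presynaptic
    spike arrives at the synapse; ``post_steps`` the postsynaptic firing
    steps.  Single pre/post neuron (index 0).
    """
    pre_set = set(int(s) for s in pre_arrival_steps)
    post_set = set(int(s) for s in post_steps)
    empty = np.empty(0, dtype=np.int64)
    unit = np.array([0], dtype=np.int64)
    for step in range(n_steps):
        now = step * dt
        delivered = unit if step in pre_set else empty
        new_post = unit if step in post_set else empty
        if delivered.size:
            rule.on_pre_delivered(delivered, now)
        if new_post.size:
            rule.on_post(new_post, now)
        rule.advance(delivered, new_post, now, dt)
    if flush:
        rule.flush((n_steps - 1) * dt)
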