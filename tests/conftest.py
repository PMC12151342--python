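import numpy as np
import pytest

from thermoplaid import bouts as tb
from thermoplaid import simulate as ts
from thermoplaid.encoder import EncoderSpec, build_inputs, train_encoder
from thermoplaid.nnet import NetSpec


@pytest.fixture(scope="session")
def plaid_policy():
    return ts.default_plaid_policy()


@pytest.fixture(scope="session")
def small_plaid_set(plaid_policy):
    """Three short plaid experiments with detected, edge-filtered bouts."""
    exps, det = [], []
    for i in range(3):
        e = ts.simulate_fish(
            plaid_policy, field=ts.PlaidField(), duration_s=240, seed=50 + i,
            exp_id=f"unit{i}",
        )
        tail = ts.synth_tail_trace(e.true_bouts, e.temperature.size, seed=60 + i)
        e.trajectory.tail_angle = tail
        b = tb.edge_filter(tb.detect_bouts(tb.swim_vigor(tail)), e.trajectory)
        exps.append(e)
        det.append(b)
    return exps, det


@pytest.fixture(scope="session")
def small_inputs(small_plaid_set):
    exps, det = small_plaid_set
    return build_inputs(exps, det)


@pytest.fixture(scope="session")
def quick_encoder(small_inputs):
    """A briefly trained encoder: adequate for gradient/shape tests, not accuracy."""
    return train_encoder(small_inputs, EncoderSpec(net=NetSpec(epochs=12)), seed=0)
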