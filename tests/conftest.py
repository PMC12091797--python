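import numpy as np
import pytest

from ymcflux import (
    ExpressionWeights,
    FluxProblem,
    split_reversible,
)
from ymcflux.synthetic_data import make_toy_network


@pytest.fixture
def diamond_pinned():
    """Diamond network with the source flux pinned to 1 (one free split)."""
    net = make_toy_network("diamond")
    src = net.reaction("SRC")
    src.lower_bound = src.upper_bound = 1.0
    return net


@pytest.fixture
def mini_cell():
    return make_toy_network("mini-cell")


def uniform_problem(net, g=None, **kwargs):
    """FluxProblem over a toy network with given (default uniform) weights."""
    irr = split_reversible(net)
    if g is None:
        g = np.ones(irr.n_components)
    weights = ExpressionWeights(g=np.asarray(g, float), component_ids=irr.component_ids)
    return FluxProblem(irr=irr, weights=weights, **kwargs)
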