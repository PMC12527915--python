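import numpy as np
import pytest

from drivergraph import DirectedGeneGraph, ModelConfig


@pytest.fixture
def chain_graph():
    """A -> B -> C."""
    return DirectedGeneGraph.from_edges(["A", "B", "C"], [(0, 1), (1, 2)])


@pytest.fixture
def tiny_config():
    """Desk-scale encoder config used by fast unit tests (float64)."""
    return ModelConfig(
        H=8,
        n_layers=2,
        n_heads=4,
        coordinate_dim=16,
        d_max=4,
        max_degree_bucket=8,
        decoder_hidden=12,
        dgp_hidden=10,
        dtype="float64",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
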