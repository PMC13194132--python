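import numpy as np
import pytest

from snnkit import Blueprint, EdgeSpec, NodeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_pool_blueprint():
    """Minimal hand-written two-node chain: LIF pool -> synapse -> LIF pool."""
    return Blueprint(
        nodes={
            "a": NodeSpec(kind="lif_pool", params={"n": 4}),
            "syn": NodeSpec(kind="traced_synapse",
                            params={"n_pre": 4, "n_post": 3, "density": 1.0,
                                    "w_max": 1.0, "d_max_ms": 3.0}),
            "b": NodeSpec(kind="lif_pool", params={"n": 3}),
        },
        edges=[
            EdgeSpec(source="a", source_port="spikes", target="syn", target_port="spikes"),
            EdgeSpec(source="syn", source_port="current", target="b", target_port="current"),
        ],
        metadata={"dt": "1.0"},
    )


@pytest.fixture
def tiny_agent_blueprint():
    """Scaled-down cartpole agent for fast training tests."""
    import snnkit

    return snnkit.cartpole_blueprint(n_exc=64, n_inh=16, n_encoder_units=16)
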