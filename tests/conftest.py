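import numpy as np
import pytest

from lmalign import TransformerConfig, TransformerLM


@pytest.fixture(scope="session")
def tiny_config():
    return TransformerConfig(
        n_layers=2, d_model=32, n_heads=4, d_ff=64, context_size=16, vocab_size=11
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return TransformerLM.init(tiny_config, seed=0)


@pytest.fixture(scope="session")
def two_state_transition():
    # asymmetric two-state chain used for entropy-rate oracles
    return np.array([[0.9, 0.1], [0.4, 0.6]])
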