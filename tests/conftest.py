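import numpy as np
import pytest

from shellscore import ShellLayout, make_toy_complex
from shellscore.graphormer import GraphormerConfig, init_graphormer_params
from shellscore.model import ScoringConfig


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(seed=1, complex_id="toy")


@pytest.fixture(scope="session")
def small_layout():
    return ShellLayout(d0=3.0, d=1.0, n_shells=2)


@pytest.fixture(scope="session")
def tiny_encoder():
    return GraphormerConfig(d_hidden=32, n_heads=2, n_layers=1, out_dim=32)


@pytest.fixture(scope="session")
def tiny_config(small_layout, tiny_encoder):
    return ScoringConfig(layout=small_layout, encoder=tiny_encoder,
                         mlp_hidden=(32, 16), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
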