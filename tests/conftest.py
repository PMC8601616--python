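import numpy as np
import pytest

from commet.fixtures import make_chain_model, make_triangle_model
from commet.model_core import FluxSpace, apply_default_bounds
from commet.preprocess import remove_blocked, run_fva


@pytest.fixture
def chain_model():
    return make_chain_model(2)


@pytest.fixture
def triangle_model():
    return make_triangle_model()


def reduced_space(model, label="base"):
    """FluxSpace with the model's own bounds, FVA-tightened and unblocked."""
    space = FluxSpace(model, label)
    return remove_blocked(space, run_fva(space))


@pytest.fixture
def chain_reduced(chain_model):
    return reduced_space(chain_model)


@pytest.fixture
def triangle_reduced(triangle_model):
    return reduced_space(triangle_model)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
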