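import numpy as np
import pytest

from milct.specs import MILHeadSpec, SynthConfig, tiny_model_spec
from milct.model import build_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained dual-branch model (96-px inputs, dims 32/64, T=1)."""
    model, n_params = build_model(tiny_model_spec(96), MILHeadSpec(m=32, l=16),
                                  seed=0)
    return model


@pytest.fixture(scope="session")
def trained_tiny():
    """Desk-scale model trained on the generator's default conditions.

    Shared by the learning-sanity check and the activation-map
    localization check; training it once keeps the suite fast.
    """
    from milct.train import learning_sanity_run

    model, report = learning_sanity_run(seed=0)
    return model, report


@pytest.fixture
def synth_cfg():
    return SynthConfig(image_size=96, n_per_class=4, seed=7)
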