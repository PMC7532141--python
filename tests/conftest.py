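import numpy as np
import pytest

from chronodense import ModelConfig, SynthSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """One stage, one block — the smallest full architecture."""
    return ModelConfig(input_channels=1, num_classes=2, blocks_per_stage=(1,),
                       growth_rate=4)


@pytest.fixture
def shrunk_config():
    """The two-stage shrunk model used for desk-scale learning checks."""
    return ModelConfig(input_channels=1, num_classes=4, blocks_per_stage=(1, 2),
                       growth_rate=8)


@pytest.fixture
def multiscale_spec():
    return SynthSpec(task="multiscale-multiclass", n_samples=400, n_classes=4,
                     sequence_length=512, noise_sigma=0.3, seed=11)


@pytest.fixture
def separable_dataset(rng):
    """Two linearly separable classes: constant-offset signals, tiny noise."""
    n, t = 60, 96
    y = np.arange(n) % 2
    x = rng.normal(0.0, 0.1, size=(n, 1, t)) + (2.0 * y - 1.0)[:, None, None]
    return x, y
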