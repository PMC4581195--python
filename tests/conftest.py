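import numpy as np
import pytest

from deepcnf.features import AminoAcidTables
from deepcnf.model import ArchitectureSpec, ModelParams
from deepcnf.types import FeatureMatrix, LabelSequence


@pytest.fixture(scope="session")
def tables():
    return AminoAcidTables.default()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_model(input_dim=4, layers=2, neurons=3, half_window=1, seed=0,
                 scale=0.5, label_weights=(1.0, 1.0), **kw):
    arch = ArchitectureSpec.create(input_dim=input_dim, layers=layers,
                                   neurons=neurons, half_window=half_window, **kw)
    return ModelParams.random(arch, seed=seed, scale=scale, label_weights=label_weights)


def random_chain(rng, length, dim):
    x = FeatureMatrix(rng.uniform(-1, 1, size=(length, dim)))
    y = LabelSequence(rng.integers(0, 2, size=length).astype(np.int8))
    return x, y
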