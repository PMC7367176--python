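import numpy as np
import pytest

from clipbind.network import ConvFilterBank, LSTMGateParams, ModelParams
from clipbind.simulate import default_spec, generate_dataset
from clipbind.training import TrainConfig, split_80_10_10, train_model


def random_model(rng, filter_sizes=(4, 5, 6, 7, 8), hidden_size=6, scale=0.3):
    """A model with randomized (non-constant) weights for forward-pass tests."""
    input_dim = 4 * (len(filter_sizes) + 1)
    conv = ConvFilterBank(
        [rng.normal(0.0, scale, size=(m, 4)) for m in filter_sizes]
    )
    return ModelParams(
        conv=conv,
        fwd=LSTMGateParams.initialize(input_dim, hidden_size, rng, std=scale),
        bwd=LSTMGateParams.initialize(input_dim, hidden_size, rng, std=scale),
    )


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture(scope="session")
def planted_dataset():
    """The default synthetic study conditions: 7-mer point-mass motif in
    every positive, 1000 + 1000 sequences of length 40."""
    spec = default_spec(seed=7)
    pos, neg, truth = generate_dataset(spec)
    return spec, pos, neg, truth


@pytest.fixture(scope="session")
def trained(planted_dataset):
    """A model trained under default config (<= 30 epochs) on the default
    fixture, with its held-out test split.  Shared across tests that need a
    genuinely trained model."""
    _, pos, neg, _ = planted_dataset
    train, val, test = split_80_10_10(pos, neg, seed=7)
    cfg = TrainConfig(max_epochs=30, seed=7)
    bundle, history = train_model(train, val, cfg)
    return bundle, history, test
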