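import copy

import numpy as np
import pytest

from protobeat import PrototypeSequenceClassifier, fixture_tiny, sequences_to_arrays
from protobeat._network import init_params
from protobeat.prototypes import PrototypeSet

# Training configuration used for the tiny noise-free fixture throughout the
# suite: small batches give enough optimiser steps on 60 beats.
TINY_FIT_KWARGS = dict(max_epochs=20, n_prototypes=4, batch_size=16,
                       validation_fraction=0.0, random_state=0)


@pytest.fixture(scope="session")
def tiny_Xy():
    seqs, recipes = fixture_tiny()
    X, y = sequences_to_arrays(seqs)
    return X, y, recipes


@pytest.fixture(scope="session")
def _fitted_tiny_model(tiny_Xy):
    X, y, _ = tiny_Xy
    clf = PrototypeSequenceClassifier(**TINY_FIT_KWARGS)
    clf.fit(X, y)
    return clf


@pytest.fixture()
def tiny_model(_fitted_tiny_model):
    """Fresh deep copy per test so editing operations cannot leak between tests."""
    return copy.deepcopy(_fitted_tiny_model)


def make_toy_model(rng, n_steps=3, length=12, hidden_size=3, n_layers=1,
                   bidirectional=True, attention_dim=2, n_prototypes=3,
                   n_classes=2, squared_distance=False):
    """A structurally valid classifier with random parameters, no training."""
    clf = PrototypeSequenceClassifier(
        n_steps=n_steps, hidden_size=hidden_size, n_layers=n_layers,
        bidirectional=bidirectional, attention_dim=attention_dim,
        n_prototypes=n_prototypes, dropout=0.0,
        squared_distance=squared_distance, random_state=0,
    )
    n_frame = length // n_steps
    u = hidden_size * (2 if bidirectional else 1)
    params = init_params(n_frame, hidden_size, n_layers, bidirectional,
                         attention_dim, n_prototypes, n_classes, rng)
    params["proto"] = rng.normal(size=(n_prototypes, u))
    params["head"] = rng.normal(size=(n_classes, n_prototypes))
    clf.params_ = params
    clf.classes_ = np.arange(n_classes)
    clf.n_features_in_ = length
    clf.prototypes_ = PrototypeSet(params["proto"])
    clf.history_ = []
    clf._epoch_offset = 0
    return clf


@pytest.fixture()
def toy_model_factory():
    return make_toy_model
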