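"""Shared fixtures: synthetic structures, the desk-scale dataset, and a
trained ensemble reused across the training-dependent tests."""

from __future__ import annotations

import numpy as np
import pytest

from rinvar.model import TrainConfig, train_ensemble
from rinvar.synthetic import SyntheticSpec, make_labeled_dataset, make_structure

#: desk-scale study conditions: L=60 helix, strong enlarge-side-chain signal,
#: 30 positives / 90 negatives (1:3 imbalance)
DESK_SPEC = SyntheticSpec()

#: desk-scale training settings: tiny stage widths, 30-epoch cap
DESK_TRAIN = dict(epochs=30, widths="tiny")


@pytest.fixture(scope="session")
def helix20():
    return make_structure(SyntheticSpec(n_residues=20))


@pytest.fixture(scope="session")
def helix60():
    return make_structure(DESK_SPEC)


@pytest.fixture(scope="session")
def desk_data():
    """Default labeled dataset: 120 interaction matrices, 25% positive."""
    return make_labeled_dataset(DESK_SPEC, 30, 90)


@pytest.fixture(scope="session")
def heldout_data():
    """Independently seeded balanced test set (40 + 40)."""
    spec = SyntheticSpec(rng_seed=7919)
    X, y, ids, meta = make_labeled_dataset(spec, 40, 40)
    return X, y


@pytest.fixture(scope="session")
def trained_ensemble(desk_data):
    X, y, _, _ = desk_data
    return train_ensemble(X, y, TrainConfig(n_estimators=3, rng_seed=0, **DESK_TRAIN))


@pytest.fixture(scope="session")
def shuffled_ensemble(desk_data):
    """Null-control model: same matrices, labels shuffled before training."""
    X, y, _, _ = desk_data
    y_shuffled = np.random.default_rng(13).permutation(y)
    return train_ensemble(X, y_shuffled,
                          TrainConfig(n_estimators=3, rng_seed=0, **DESK_TRAIN))
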