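"""Architecture identity, undersampling contracts, ensemble arithmetic,
persistence, and training-loop mechanics (fast, desk-scale settings)."""

import numpy as np
import pytest

from rinvar.model import (
    ArchitectureSpec,
    ResNetClassifier2D,
    UndersampleEnsembleClassifier,
    build_base_classifier,
    undersample_subsets,
)
from rinvar.nn import ResNet, softmax_cross_entropy


# --------------------------------------------------------------------------
# parameter-count identity
# --------------------------------------------------------------------------

def test_full_architecture_parameter_count():
    """The canonical 7-channel 2-class network has exactly 11,194,882
    trainable parameters (conv biases on, BN gamma+beta trainable)."""
    net, n_params = build_base_classifier(ArchitectureSpec.full())
    assert n_params == 11_194_882


def test_parameter_count_layerwise_oracle_3ch_1000cls():
    """Independent layer-by-layer arithmetic for the 3-channel, 1000-class
    variant: 11,689,512 (standard weight count) + 4,800 conv biases."""
    net, n_params = build_base_classifier(
        ArchitectureSpec(in_channels=3, n_classes=1000))
    assert n_params == 11_694_312


def test_parameter_count_independent_of_input_size():
    """Fully convolutional + global pooling: L never enters the count."""
    net, n_params = build_base_classifier(ArchitectureSpec.tiny())
    x_small = np.zeros((1, 16, 16, 7))
    x_large = np.zeros((1, 24, 24, 7))
    assert net.forward(x_small).shape == (1, 2)
    assert net.forward(x_large).shape == (1, 2)
    assert net.n_params() == n_params


def test_non_square_input_rejected():
    net, _ = build_base_classifier(ArchitectureSpec.tiny())
    with pytest.raises(ValueError, match="square"):
        net.forward(np.zeros((1, 16, 20, 7)))


# --------------------------------------------------------------------------
# numeric gradient spot check of the layer framework
# --------------------------------------------------------------------------

def test_backprop_matches_numeric_gradient():
    net = ResNet(3, 2, widths=(2, 3, 4, 5), seed=1)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(3, 12, 12, 3))
    y = np.array([0, 1, 1])
    logits = net.forward(x, training=True)
    _, dlogits = softmax_cross_entropy(logits, y)
    net.backward(dlogits)
    params = list(net.parameters())
    picks = np.random.default_rng(2).choice(len(params), size=5, replace=False)
    for key, layer, name, arr in (params[int(k)] for k in picks):
        flat = arr.ravel()
        idx = int(np.random.default_rng(hash(key) % 2**31).integers(flat.size))
        eps, orig = 1e-6, flat[idx]
        flat[idx] = orig + eps
        lp, _ = softmax_cross_entropy(net.forward(x, training=True), y)
        flat[idx] = orig - eps
        lm, _ = softmax_cross_entropy(net.forward(x, training=True), y)
        flat[idx] = orig
        numeric = (lp - lm) / (2 * eps)
        analytic = layer.grads[name].ravel()[idx]
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


# --------------------------------------------------------------------------
# EasyEnsemble undersampling
# --------------------------------------------------------------------------

def test_undersample_subsets_published_cardinality():
    """|P|=260, |N|=800, T=3: three sets of 520, each with all positives."""
    P = np.arange(260)
    N = np.arange(260, 1060)
    subsets = undersample_subsets(P, N, T=3, seed=0)
    assert len(subsets) == 3
    for s in subsets:
        assert len(s) == 520
        assert set(P) <= set(s)
        negs = [i for i in s if i >= 260]
        assert len(negs) == len(set(negs)) == 260  # without replacement
    # independent draws: the three negative sets are not all identical
    neg_sets = [frozenset(i for i in s if i >= 260) for s in subsets]
    assert len(set(neg_sets)) > 1


def test_undersample_degenerate_balance_and_determinism():
    P, N = np.arange(5), np.arange(5, 10)
    subsets = undersample_subsets(P, N, T=2, seed=3)
    for s in subsets:
        assert sorted(s) == list(range(10))
    again = undersample_subsets(P, N, T=2, seed=3)
    for a, b in zip(subsets, again):
        np.testing.assert_array_equal(a, b)


def test_undersample_rejects_minority_majority_swap():
    with pytest.raises(ValueError, match="swap roles"):
        undersample_subsets(np.arange(10), np.arange(10, 15), T=2, seed=0)


# --------------------------------------------------------------------------
# ensemble probability arithmetic
# --------------------------------------------------------------------------

class _StubClassifier:
    def __init__(self, p1):
        self.p1 = p1

    def predict_proba(self, X):
        return np.tile([1.0 - self.p1, self.p1], (len(X), 1))


def test_ensemble_probability_is_mean_of_base_probabilities():
    ens = UndersampleEnsembleClassifier(n_estimators=3)
    ens.classes_ = np.array([0, 1])
    ens.estimators_ = [_StubClassifier(p) for p in (0.9, 0.8, 0.1)]
    X = np.zeros((2, 4, 4, 7))
    probs = ens.predict_proba(X)[:, 1]
    np.testing.assert_allclose(probs, 0.6)
    assert list(ens.predict(X)) == [1, 1]  # 0.6 >= 0.5: pathogenic


def test_single_member_ensemble_equals_base(tiny_fit_data):
    X, y = tiny_fit_data
    base = ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=2, batch_size=8,
                              random_state=0)
    ens = UndersampleEnsembleClassifier(base, n_estimators=1, random_state=5)
    ens.fit(X, y)
    solo = ens.estimators_[0]
    np.testing.assert_array_equal(ens.predict_proba(X),
                                  solo.predict_proba(X))


# --------------------------------------------------------------------------
# training mechanics
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_fit_data():
    rng = np.random.default_rng(1)
    half = rng.random((24, 10, 10, 7))
    X = half + half.transpose(0, 2, 1, 3)
    y = np.repeat([0, 1], 12)
    X[y == 1, :, :, 4] += 1.0  # weak channel-5 signal
    for k in range(len(X)):
        X[k][np.arange(10), np.arange(10), :] = 0.0
    return X, y


def test_fit_determinism_same_seed(tiny_fit_data):
    X, y = tiny_fit_data
    runs = []
    for _ in range(2):
        clf = ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=2, batch_size=8,
                                 random_state=42)
        clf.fit(X, y)
        runs.append(clf)
    assert runs[0].history_[0]["train_loss"] == runs[1].history_[0]["train_loss"]
    np.testing.assert_array_equal(runs[0].val_indices_, runs[1].val_indices_)
    np.testing.assert_array_equal(runs[0].predict_proba(X),
                                  runs[1].predict_proba(X))


def test_ensemble_subset_determinism(tiny_fit_data):
    X, y = tiny_fit_data
    base = ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=1, batch_size=8)
    a = UndersampleEnsembleClassifier(base, n_estimators=2, random_state=9).fit(X, y)
    b = UndersampleEnsembleClassifier(base, n_estimators=2, random_state=9).fit(X, y)
    for sa, sb in zip(a.subsets_, b.subsets_):
        np.testing.assert_array_equal(sa, sb)


def test_save_load_predict_bit_stable(tiny_fit_data, tmp_path):
    X, y = tiny_fit_data
    clf = ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=2, batch_size=8,
                             random_state=7)
    clf.fit(X, y)
    clf.save(tmp_path / "model")
    back = ResNetClassifier2D.load(tmp_path / "model")
    np.testing.assert_array_equal(clf.predict_proba(X), back.predict_proba(X))


def test_ensemble_save_load_round_trip(tiny_fit_data, tmp_path):
    X, y = tiny_fit_data
    base = ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=2, batch_size=8)
    ens = UndersampleEnsembleClassifier(base, n_estimators=2, random_state=1)
    ens.fit(X, y)
    ens.save(tmp_path / "ens")
    back = UndersampleEnsembleClassifier.load(tmp_path / "ens")
    np.testing.assert_array_equal(ens.predict_proba(X), back.predict_proba(X))
    for sa, sb in zip(ens.subsets_, back.subsets_):
        np.testing.assert_array_equal(sa, sb)


def test_single_class_rejected(tiny_fit_data):
    X, y = tiny_fit_data
    with pytest.raises(ValueError, match="single class"):
        ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=1).fit(X, np.zeros(len(X)))
    with pytest.raises(ValueError, match="two classes"):
        UndersampleEnsembleClassifier(n_estimators=1).fit(X, np.zeros(len(X)))


def test_nan_loss_aborts_with_diagnostic(tiny_fit_data):
    X, y = tiny_fit_data
    bad = X.copy()
    bad[0, 0, 1, 0] = bad[0, 1, 0, 0] = np.inf  # poisons the stem activations
    with pytest.raises(RuntimeError, match="non-finite"):
        ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=1, batch_size=24,
                           random_state=0).fit(bad, y)


def test_predict_shape_validation(tiny_fit_data):
    X, y = tiny_fit_data
    clf = ResNetClassifier2D(widths=(2, 2, 2, 2), epochs=1, batch_size=8,
                             random_state=0)
    clf.fit(X, y)
    with pytest.raises(ValueError, match="does not match"):
        clf.predict_proba(np.zeros((2, 12, 12, 7)))
    with pytest.raises(ValueError, match="square"):
        clf.predict_proba(np.zeros((2, 10, 12, 7)))


def test_early_stopping_within_patience(trained_ensemble):
    """Training halts no more than `patience` epochs after the best
    validation loss (or runs to the epoch cap)."""
    for est in trained_ensemble.estimators_:
        assert est.stopped_epoch_ - est.best_epoch_ <= est.patience
        assert est.best_epoch_ >= 0


def test_history_records_both_splits(trained_ensemble):
    for est in trained_ensemble.estimators_:
        h = est.history_
        assert len(h) >= 1
        for row in h:
            assert {"epoch", "train_loss", "train_acc",
                    "val_loss", "val_acc"} <= row.keys()
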