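"""Base CNN classifier and under-sampled ensemble for interaction matrices.

The base classifier is a ResNet18-style 2D CNN (see :mod:`rinvar.nn.resnet`)
wrapped as a scikit-learn estimator; the ensemble follows the EasyEnsemble
recipe for class imbalance: T balanced training sets, each holding every
minority (pathogenic) example plus an equal-sized draw from the majority
class without replacement, one base classifier per set, and the mean of
their class-1 probabilities as the ensemble score (decision threshold 0.5).

Training mirrors the published recipe: Adadelta, batch size 26, up to 200
epochs, a stratified 10% validation split, and early stopping on validation
loss with patience 10 (best weights restored).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .nn import Adadelta, ResNet, softmax, softmax_cross_entropy
from .nn.resnet import FULL_WIDTHS, TINY_WIDTHS

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "build_base_classifier",
    "undersample_subsets",
    "ResNetClassifier2D",
    "UndersampleEnsembleClassifier",
    "train_ensemble",
    "ensemble_predict",
    "cross_train_filter",
]

_PRESET_WIDTHS = {"full": FULL_WIDTHS, "tiny": TINY_WIDTHS}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Static description of one base classifier network."""

    in_channels: int = 7
    n_classes: int = 2
    widths: tuple[int, ...] = FULL_WIDTHS
    leaky_slope: float = 0.3

    @classmethod
    def full(cls) -> "ArchitectureSpec":
        return cls()

    @classmethod
    def tiny(cls) -> "ArchitectureSpec":
        return cls(widths=TINY_WIDTHS)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (defaults follow the published recipe)."""

    epochs: int = 200
    batch_size: int = 26
    early_stop_patience: int = 10
    val_fraction: float = 0.10
    n_estimators: int = 3           # T base classifiers
    widths: str | tuple[int, ...] = "full"
    rng_seed: int = 0
    lr: float = 1.0                 # Adadelta base step
    rho: float = 0.95
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.n_estimators < 1:
            raise ValueError("need at least one base classifier")


def build_base_classifier(spec: ArchitectureSpec, seed: int = 0) -> tuple[ResNet, int]:
    """Construct an untrained base network; returns (network, parameter count)."""
    net = ResNet(spec.in_channels, spec.n_classes, widths=spec.widths,
                 leaky=spec.leaky_slope, seed=seed)
    return net, net.n_params()


def undersample_subsets(positives: np.ndarray, negatives: np.ndarray,
                        T: int, seed: int) -> list[np.ndarray]:
    """T balanced index sets: all positives + |P| negatives drawn w/o replacement.

    Draws are independent across the T subsets and reproducible under
    ``seed``.  Requires |N| >= |P|.
    """
    P = np.asarray(positives)
    N = np.asarray(negatives)
    if len(P) < 1:
        raise ValueError("need at least one positive example")
    if len(N) < len(P):
        raise ValueError(
            f"majority class smaller than minority ({len(N)} < {len(P)}); "
            "swap roles before calling")
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(T):
        ni = rng.choice(N, size=len(P), replace=False)
        subsets.append(np.concatenate([P, ni]))
    return subsets


def _resolve_widths(widths) -> tuple[int, ...]:
    if isinstance(widths, str):
        try:
            return _PRESET_WIDTHS[widths]
        except KeyError:
            raise ValueError(f"unknown width preset {widths!r}") from None
    return tuple(widths)


class ResNetClassifier2D(BaseEstimator, ClassifierMixin):
    """Scikit-learn classifier over square multi-channel interaction maps.

    ``X`` has shape (n_samples, L, L, C); ``y`` is binary.  ``widths`` is a
    preset name (``"full"`` = 64/128/256/512, ``"tiny"`` = 8/16/32/64) or an
    explicit tuple of the four stage widths.
    """

    def __init__(self, widths: str | tuple[int, ...] = "full", epochs: int = 200,
                 batch_size: int = 26, patience: int = 10,
                 val_fraction: float = 0.10, leaky_slope: float = 0.3,
                 lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6,
                 random_state: int | None = None, verbose: int = 0) -> None:
        self.widths = widths
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.leaky_slope = leaky_slope
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.random_state = random_state
        self.verbose = verbose

    # -- internals ----------------------------------------------------------
    def _validate_X(self, X, fitted: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[1] != X.shape[2]:
            raise ValueError(f"X must be (n, L, L, C) with square maps, got {X.shape}")
        if fitted and X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"X shape {X.shape[1:]} does not match training shape "
                f"{self.input_shape_}")
        return X

    def _stratified_split(self, y: np.ndarray, rng: np.random.Generator):
        val_idx = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            n_val = max(1, int(round(self.val_fraction * len(idx)))) if len(idx) > 1 else 0
            val_idx.extend(idx[:n_val])
        val = np.sort(np.array(val_idx, dtype=int))
        train = np.setdiff1d(np.arange(len(y)), val)
        return train, val

    def _batched_logits(self, net: ResNet, X: np.ndarray, chunk: int = 64) -> np.ndarray:
        outs = [net.forward(X[k : k + chunk], training=False)
                for k in range(0, len(X), chunk)]
        return np.concatenate(outs, axis=0)

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y) -> "ResNetClassifier2D":
        X = self._validate_X(X, fitted=False)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        yi = np.searchsorted(self.classes_, y)
        self.input_shape_ = X.shape[1:]

        seed = self.random_state if self.random_state is not None else 0
        rng = np.random.default_rng(seed)
        net = ResNet(X.shape[3], 2, widths=_resolve_widths(self.widths),
                     leaky=self.leaky_slope, seed=int(rng.integers(2**31)))
        self.n_params_ = net.n_params()
        opt = Adadelta(lr=self.lr, rho=self.rho, eps=self.eps)

        tr_idx, va_idx = self._stratified_split(yi, rng)
        Xtr, ytr = X[tr_idx], yi[tr_idx]
        Xva, yva = X[va_idx], yi[va_idx]

        history: list[dict] = []
        best_val = np.inf
        best_state = None
        best_epoch = -1
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            losses, correct = [], 0
            for k in range(0, len(order), self.batch_size):
                batch = order[k : k + self.batch_size]
                logits = net.forward(Xtr[batch], training=True)
                loss, dlogits = softmax_cross_entropy(logits, ytr[batch])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(batch starting {k}); aborting")
                net.backward(dlogits)
                opt.step(net.parameters())
                losses.append(loss * len(batch))
                correct += int((logits.argmax(axis=1) == ytr[batch]).sum())
            train_loss = float(np.sum(losses) / len(order))
            train_acc = correct / len(order)

            if len(Xva):
                vlogits = self._batched_logits(net, Xva)
                val_loss, _ = softmax_cross_entropy(vlogits, yva)
                val_acc = float((vlogits.argmax(axis=1) == yva).mean())
            else:
                val_loss, val_acc = train_loss, train_acc
            history.append(dict(epoch=epoch, train_loss=train_loss,
                                train_acc=train_acc, val_loss=val_loss,
                                val_acc=val_acc))
            if self.verbose:
                print(f"epoch {epoch}: train {train_loss:.4f}/{train_acc:.3f} "
                      f"val {val_loss:.4f}/{val_acc:.3f}")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_epoch = epoch
                best_state = {k: v.copy() for k, v in net.state_dict().items()}
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.stopped_epoch_ = history[-1]["epoch"]
        self.val_indices_ = va_idx
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_X(X, fitted=True)
        return softmax(self._batched_logits(self.net_, X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    # -- persistence ---------------------------------------------------------
    def save(self, path_prefix: str | Path) -> None:
        """Write weights to ``<prefix>.npz`` and metadata to ``<prefix>.json``."""
        prefix = Path(path_prefix)
        np.savez(prefix.with_suffix(".npz"), **self.net_.state_dict())
        meta = dict(params=self.get_params(),
                    classes=self.classes_.tolist(),
                    input_shape=list(self.input_shape_),
                    n_params=self.n_params_,
                    best_epoch=self.best_epoch_,
                    history=self.history_)
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path_prefix: str | Path) -> "ResNetClassifier2D":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        params = meta["params"]
        if isinstance(params.get("widths"), list):
            params["widths"] = tuple(params["widths"])
        est = cls(**params)
        est.classes_ = np.array(meta["classes"])
        est.input_shape_ = tuple(meta["input_shape"])
        est.n_params_ = meta["n_params"]
        est.best_epoch_ = meta["best_epoch"]
        est.history_ = meta["history"]
        est.stopped_epoch_ = meta["history"][-1]["epoch"] if meta["history"] else -1
        est.val_indices_ = np.array([], dtype=int)
        net = ResNet(est.input_shape_[2], 2, widths=_resolve_widths(est.widths),
                     leaky=est.leaky_slope, seed=0)
        with np.load(prefix.with_suffix(".npz")) as state:
            net.load_state_dict(dict(state))
        est.net_ = net
        return est


class UndersampleEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """EasyEnsemble-style ensemble of base CNN classifiers.

    Fits ``n_estimators`` clones of ``base_estimator`` on balanced
    undersampled index sets (all positives + equal negative draws) and
    averages their class-1 probabilities.  Class 1 is treated as the
    minority/positive class; the majority class must be at least as large.
    """

    def __init__(self, base_estimator: ResNetClassifier2D | None = None,
                 n_estimators: int = 3, random_state: int | None = None) -> None:
        self.base_estimator = base_estimator
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y) -> "UndersampleEnsembleClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ensemble requires exactly two classes")
        yi = np.searchsorted(self.classes_, y)
        P = np.flatnonzero(yi == 1)
        N = np.flatnonzero(yi == 0)
        seed = self.random_state if self.random_state is not None else 0
        self.subsets_ = undersample_subsets(P, N, self.n_estimators, seed)
        proto = self.base_estimator if self.base_estimator is not None \
            else ResNetClassifier2D(widths="tiny")
        rng = np.random.default_rng(seed)
        base_seeds = rng.integers(2**31, size=self.n_estimators)
        self.estimators_ = []
        for t, subset in enumerate(self.subsets_):
            est = clone(proto)
            est.set_params(random_state=int(base_seeds[t]))
            est.fit(X[subset], yi[subset])
            self.estimators_.append(est)
        return self

    def predict_proba(self, X) -> np.ndarray:
        probs = np.mean([est.predict_proba(X) for est in self.estimators_], axis=0)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for t, est in enumerate(self.estimators_):
            est.save(d / f"base_{t}")
        meta = dict(params={"n_estimators": self.n_estimators,
                            "random_state": self.random_state},
                    classes=self.classes_.tolist(),
                    subsets=[s.tolist() for s in self.subsets_])
        (d / "ensemble.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "UndersampleEnsembleClassifier":
        d = Path(directory)
        meta = json.loads((d / "ensemble.json").read_text())
        ens = cls(**meta["params"])
        ens.classes_ = np.array(meta["classes"])
        ens.subsets_ = [np.array(s) for s in meta["subsets"]]
        ens.estimators_ = [ResNetClassifier2D.load(d / f"base_{t}")
                           for t in range(meta["params"]["n_estimators"])]
        return ens


# --------------------------------------------------------------------------
# Procedural wrappers
# --------------------------------------------------------------------------

def train_ensemble(X: np.ndarray, y: np.ndarray,
                   cfg: TrainConfig | None = None) -> UndersampleEnsembleClassifier:
    """Train an EasyEnsemble model from a labeled interaction-matrix dataset."""
    cfg = cfg or TrainConfig()
    base = ResNetClassifier2D(
        widths=cfg.widths, epochs=cfg.epochs, batch_size=cfg.batch_size,
        patience=cfg.early_stop_patience, val_fraction=cfg.val_fraction,
        lr=cfg.lr, rho=cfg.rho, eps=cfg.eps)
    ens = UndersampleEnsembleClassifier(base, n_estimators=cfg.n_estimators,
                                        random_state=cfg.rng_seed)
    return ens.fit(X, y)


def ensemble_predict(model: UndersampleEnsembleClassifier,
                     X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble class-1 probability and the 0.5-threshold class call."""
    probs = model.predict_proba(X)[:, 1]
    return probs, (probs >= 0.5).astype(int)


def cross_train_filter(train_X: np.ndarray, train_y: np.ndarray,
                       probe_X: np.ndarray, probe_y: np.ndarray,
                       variant_ids: list[str] | None = None,
                       extreme_cut: float = 0.95,
                       estimator: BaseEstimator | None = None,
                       random_state: int = 0):
    """Flag and drop training samples misclassified with extreme confidence.

    A model trained on the independent ``probe`` set scores the training
    set; samples whose wrong-class probability is at least ``extreme_cut``
    are removed (suspected label errors).  At most 5% of the training set is
    ever removed — if more are flagged, only the most extreme are dropped.

    Returns ``(keep_mask, report)`` where report is a list of dicts with
    variant id, label, wrong-class probability and removal flag.
    """
    train_y = np.asarray(train_y)
    probe_y = np.asarray(probe_y)
    if len(np.unique(probe_y)) < 2:
        raise ValueError("probe set must contain both classes")
    ids = variant_ids or [f"sample_{k}" for k in range(len(train_y))]
    model = estimator or UndersampleEnsembleClassifier(
        ResNetClassifier2D(widths="tiny"), random_state=random_state)
    model.fit(probe_X, probe_y)
    p1 = model.predict_proba(train_X)[:, 1]
    wrong_prob = np.where(train_y == 1, 1.0 - p1, p1)
    if extreme_cut >= 1.0:
        # a probability can saturate to 1.0 in floating point; a cut of 1.0
        # is documented as vacuous and removes nothing
        flagged = np.array([], dtype=int)
    else:
        flagged = np.flatnonzero(wrong_prob >= extreme_cut)
    max_remove = int(0.05 * len(train_y))
    removed = flagged[np.argsort(-wrong_prob[flagged])][:max_remove]
    keep = np.ones(len(train_y), dtype=bool)
    keep[removed] = False
    report = [dict(variant_id=ids[k], label=int(train_y[k]),
                   wrong_class_prob=float(wrong_prob[k]),
                   removed=bool(not keep[k]))
              for k in flagged]
    return keep, report
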