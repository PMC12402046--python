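"""RBNet: a lightweight repeating-block 3D CNN nodule classifier.

The network is four identical blocks — 3D convolution, batch
normalization, ReLU, 2x2x2 max pooling — with filter counts rising from
64 in the first block to 256 in the last, followed by global average
pooling, dropout and a single sigmoid unit (label 1 = nodule,
0 = non-nodule).  Training uses Adam on binary cross-entropy with an
exponential learning-rate schedule (``lr0 * decay^epoch``); the weights
with the lowest validation loss are retained.

One instance is trained per dose level; :func:`train_per_dose` builds the
registry the ensemble consumes.

:class:`RBNetClassifier` follows the scikit-learn estimator protocol
(``fit`` / ``predict_proba`` / ``get_params``) so it composes with
pipelines and model selection.  A reduced preset
(:meth:`RBNetClassifier.ci_preset`: filters scaled by 1/8, 32-voxel
patches) keeps CPU training tractable; full size is the default config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._nn import (Adam, BatchNorm3D, Conv3D, Dense, Dropout, GlobalAvgPool,
                  MaxPool3D, ReLU, Sequential3D, bce_with_logits, sigmoid)

__all__ = ["RBNetSpec", "TrainConfig", "RBNetClassifier", "build_model",
           "split_dataset", "train_model", "predict_proba", "train_per_dose",
           "DOSE_FRACTIONS"]

DOSE_FRACTIONS = (1.0, 0.6, 0.4, 0.2, 0.1)


@dataclass
class RBNetSpec:
    """Architecture description; ``scale`` shrinks filter counts for
    reduced test-size presets (scale 1/8 -> 8/16/24/32 filters)."""

    n_blocks: int = 4
    filters_per_block: tuple[int, ...] = (64, 128, 192, 256)
    kernel: int = 3
    dropout_rate: float = 0.3
    input_side: int = 64
    scale: float = 1.0

    def scaled_filters(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(f * self.scale))) for f in self.filters_per_block)

    def __post_init__(self) -> None:
        if len(self.filters_per_block) != self.n_blocks:
            raise ValueError("filters_per_block length must equal n_blocks")
        if self.input_side % (2 ** self.n_blocks) != 0:
            raise ValueError(
                f"input_side {self.input_side} must be divisible by 2^{self.n_blocks}")


@dataclass
class TrainConfig:
    """Optimization recipe (full-size defaults)."""

    learning_rate: float = 1e-4
    decay_factor: float = 0.96
    epochs: int = 40
    batch_size: int = 16
    train_fraction: float = 0.6
    augment: bool = False
    n_restarts: int = 1
    restart_val_loss: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class RBNetClassifier(ClassifierMixin, BaseEstimator):
    """Repeating-block 3D CNN binary classifier.

    Parameters mirror :class:`RBNetSpec` and :class:`TrainConfig` as flat
    keyword arguments per scikit-learn convention.

    Attributes (after ``fit``)
    --------------------------
    net_ : internal layer stack with the best-validation-loss weights
    history_ : dict of per-epoch ``loss`` / ``accuracy`` / ``val_loss`` /
        ``val_accuracy`` / ``lr`` lists
    classes_ : ndarray [0, 1]
    best_epoch_ : epoch index whose weights were retained
    """

    def __init__(self, filters_per_block=(64, 128, 192, 256), input_side=64,
                 kernel=3, dropout_rate=0.3, learning_rate=1e-4,
                 decay_factor=0.96, epochs=40, batch_size=16, augment=False,
                 n_restarts=1, restart_val_loss=None, random_state=0, verbose=0):
        self.filters_per_block = filters_per_block
        self.input_side = input_side
        self.kernel = kernel
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.decay_factor = decay_factor
        self.epochs = epochs
        self.batch_size = batch_size
        self.augment = augment
        self.n_restarts = n_restarts
        self.restart_val_loss = restart_val_loss
        self.random_state = random_state
        self.verbose = verbose

    @classmethod
    def ci_preset(cls, **overrides) -> "RBNetClassifier":
        """Reduced configuration: 1/8-scale filters, 32-voxel patches.

        The learning rate is raised to 3e-3 (batch 8) to compensate for
        the roughly 30x fewer optimizer steps of the small preset; see
        the methods note.
        """
        params = dict(filters_per_block=(8, 16, 24, 32), input_side=32,
                      learning_rate=3e-3, batch_size=8, epochs=10, augment=True,
                      n_restarts=2, restart_val_loss=0.35)
        params.update(overrides)
        return cls(**params)

    # ------------------------------------------------------------------ build
    def _build_net(self, rng: np.random.Generator) -> Sequential3D:
        n_blocks = len(self.filters_per_block)
        if self.input_side % (2 ** n_blocks) != 0:
            raise ValueError(
                f"input_side {self.input_side} must be divisible by 2^{n_blocks}")
        layers = []
        c_in = 1
        for f in self.filters_per_block:
            layers += [Conv3D(c_in, f, kernel=self.kernel, rng=rng),
                       BatchNorm3D(f), ReLU(), MaxPool3D()]
            c_in = f
        layers += [GlobalAvgPool(), Dropout(self.dropout_rate), Dense(c_in, 1, rng=rng)]
        return Sequential3D(layers)

    def initialize(self, random_state=None) -> "RBNetClassifier":
        """Build an untrained network (for forward-pass use without fit)."""
        seed = self.random_state if random_state is None else random_state
        rng = np.random.default_rng(seed)
        self.net_ = self._build_net(rng)
        self.classes_ = np.array([0, 1])
        self.history_ = {}
        return self

    # ------------------------------------------------------------------- data
    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4:
            X = X[:, None]
        if X.ndim != 5 or X.shape[1] != 1:
            raise ValueError(f"X must be (n, side, side, side), got {X.shape}")
        s = self.input_side
        if X.shape[2:] != (s, s, s):
            raise ValueError(f"patches must be {s}^3 to match input_side, got {X.shape[2:]}")
        return X

    # -------------------------------------------------------------------- fit
    def fit(self, X, y, validation_data=None):
        """Train the network; optional ``validation_data=(X_val, y_val)``.

        With validation data, the weights from the epoch with the lowest
        validation loss are retained.  If ``restart_val_loss`` is set and
        that loss stays above it, training restarts from a fresh derived
        init (up to ``n_restarts`` attempts total) and the attempt with
        the lowest validation loss wins — a guard against the occasional
        bad initialization on very small training sets.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        y = y.astype(np.float64)
        if len(X) == 0:
            raise ValueError("empty training set")
        has_val = validation_data is not None
        attempts = max(1, self.n_restarts) if has_val else 1
        best = None
        for attempt, ss in enumerate(np.random.SeedSequence(self.random_state).spawn(attempts)):
            run = self._fit_once(ss, X, y, validation_data)
            if best is None or run["best_val"] < best["best_val"]:
                best = run
            if (self.restart_val_loss is None
                    or best["best_val"] <= self.restart_val_loss):
                break
        self.net_ = best["net"]
        self.history_ = best["hist"]
        self.best_epoch_ = best["best_epoch"]
        self.classes_ = np.array([0, 1])
        return self

    def _fit_once(self, ss, X, y, validation_data):
        init_rng, shuffle_rng, drop_rng, aug_rng = (np.random.default_rng(s)
                                                    for s in ss.spawn(4))
        self.net_ = self._build_net(init_rng)
        opt = Adam(self.net_.parameters())

        has_val = validation_data is not None
        if has_val:
            X_val = self._check_X(validation_data[0])
            y_val = np.asarray(validation_data[1], dtype=np.float64)
        hist = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [], "lr": []}
        best_state, best_val, best_epoch = None, np.inf, -1

        n = len(X)
        for epoch in range(self.epochs):
            lr = self.learning_rate * self.decay_factor ** epoch
            order = shuffle_rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                if self.augment:
                    xb = _augment_batch(xb, aug_rng)
                logits = self.net_.forward(xb, train=True, rng=drop_rng)[:, 0]
                loss, dlogits = bce_with_logits(logits, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch}, batch starting {start}; "
                        "lower the learning rate")
                self.net_.backward(dlogits[:, None])
                opt.step(lr)
                losses.append(loss * len(idx))
                correct += int(np.sum((sigmoid(logits) >= 0.5) == yb))
            hist["loss"].append(float(np.sum(losses) / n))
            hist["accuracy"].append(correct / n)
            hist["lr"].append(lr)
            if has_val:
                pv = self._forward_eval(X_val)
                logit_v = np.log(pv / (1 - pv))
                vl, _ = bce_with_logits(logit_v, y_val)
                va = float(np.mean((pv >= 0.5) == y_val))
                hist["val_loss"].append(vl)
                hist["val_accuracy"].append(va)
                if vl < best_val:
                    best_val, best_epoch = vl, epoch
                    best_state = self.net_.get_state()
            if self.verbose:
                msg = f"epoch {epoch:3d}  lr {lr:.2e}  loss {hist['loss'][-1]:.4f}  acc {hist['accuracy'][-1]:.3f}"
                if has_val:
                    msg += f"  val_loss {hist['val_loss'][-1]:.4f}  val_acc {hist['val_accuracy'][-1]:.3f}"
                print(msg)
        if best_state is not None:
            self.net_.set_state(best_state)
        else:
            best_epoch = self.epochs - 1
            best_val = hist["loss"][-1]
        return {"net": self.net_, "hist": hist, "best_val": best_val,
                "best_epoch": best_epoch}

    # -------------------------------------------------------------- inference
    def _forward_eval(self, X, chunk: int = 32) -> np.ndarray:
        out = np.empty(len(X), dtype=np.float64)
        for start in range(0, len(X), chunk):
            logits = self.net_.forward(X[start:start + chunk], train=False)[:, 0]
            out[start:start + len(logits)] = sigmoid(logits)
        # keep strictly inside (0, 1) so logits/logs stay finite
        return np.clip(out, 1e-12, 1.0 - 1e-12)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        p1 = self._forward_eval(self._check_X(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random cube symmetries that preserve the axial-plane geometry:
    flips along each axis plus an optional in-plane (x/y) transpose."""
    out = np.empty_like(xb)
    for i in range(len(xb)):
        v = xb[i, 0]
        code = rng.integers(16)
        if code & 1:
            v = v[::-1]
        if code & 2:
            v = v[:, ::-1]
        if code & 4:
            v = v[:, :, ::-1]
        if code & 8:
            v = v.transpose(1, 0, 2)
        out[i, 0] = v
    return out


# ---------------------------------------------------------------- module ops

def build_model(spec: RBNetSpec, train_cfg: TrainConfig | None = None,
                seed: int | None = None) -> RBNetClassifier:
    """Instantiate an (untrained but runnable) classifier from a spec."""
    cfg = train_cfg or TrainConfig()
    model = RBNetClassifier(
        filters_per_block=spec.scaled_filters(), input_side=spec.input_side,
        kernel=spec.kernel, dropout_rate=spec.dropout_rate,
        learning_rate=cfg.learning_rate, decay_factor=cfg.decay_factor,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        random_state=cfg.seed if seed is None else seed)
    return model.initialize()


def split_dataset(patches, labels, cfg: TrainConfig):
    """Stratified train/validation/test split (train_fraction, rest halved).

    With the default 0.6 train fraction this is the 60/20/20 protocol;
    the three parts are disjoint and their union is the input set.
    """
    labels = np.asarray(labels)
    for cls in (0, 1):
        if not np.any(labels == cls):
            raise ValueError(f"class {cls} absent from labels")
    idx = np.arange(len(labels))
    tr, rest = train_test_split(idx, train_size=cfg.train_fraction,
                                stratify=labels, random_state=cfg.seed)
    val, te = train_test_split(rest, train_size=0.5, stratify=labels[rest],
                               random_state=cfg.seed + 1)
    patches = np.asarray(patches)
    return ((patches[tr], labels[tr]), (patches[val], labels[val]),
            (patches[te], labels[te]))


def train_model(model: RBNetClassifier, train, validation, cfg: TrainConfig):
    """Fit ``model`` on a (X, y) train set with per-epoch validation."""
    model.set_params(learning_rate=cfg.learning_rate, decay_factor=cfg.decay_factor,
                     epochs=cfg.epochs, batch_size=cfg.batch_size)
    model.fit(train[0], train[1], validation_data=validation)
    return model, model.history_


def predict_proba(model: RBNetClassifier, patches) -> np.ndarray:
    """Probability of the nodule class, one value per patch."""
    return model.predict_proba(patches)[:, 1]


def train_per_dose(datasets: Mapping[float, tuple], cfg: TrainConfig,
                   model_factory=None,
                   expected_fractions: Sequence[float] = DOSE_FRACTIONS,
                   validation: Mapping[float, tuple] | None = None):
    """Train one independent model per dose level.

    ``datasets`` maps dose fraction to its own ``(patches, labels)``;
    each model sees only its level's data.  Raises if any expected level
    is missing.  Returns ``{fraction: fitted model}``.
    """
    missing = [f for f in expected_fractions if f not in datasets]
    if missing:
        raise ValueError(f"missing dose levels: {missing}")
    if model_factory is None:
        model_factory = lambda: RBNetClassifier(
            learning_rate=cfg.learning_rate, decay_factor=cfg.decay_factor,
            epochs=cfg.epochs, batch_size=cfg.batch_size, augment=cfg.augment,
            n_restarts=cfg.n_restarts, restart_val_loss=cfg.restart_val_loss)
    registry: dict[float, RBNetClassifier] = {}
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(len(expected_fractions))
    for frac, seed in zip(expected_fractions, child_seeds):
        X, y = datasets[frac]
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError(f"dose level {frac} lacks one of the classes")
        model = model_factory()
        model.set_params(random_state=int(seed % (2**31 - 1)))
        val = validation[frac] if validation is not None else None
        model.fit(X, y, validation_data=val)
        registry[frac] = model
    return registry
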