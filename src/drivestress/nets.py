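"""1D CNN and hybrid 1D CNN-LSTM stress classifiers.

Architectures are declarative (:class:`NetworkSpec`) and follow the device
profiles of the driver-stress study the package models:

* ``srad``, ``e4l``, ``e4r``, ``e4lr``, ``bh_e4lr`` — four convolutional
  blocks with 8/32/64/128 filters plus a trailing 8-filter convolution;
* ``bh`` — three blocks with 128/64/32 filters, no trailing convolution.

Every block is Conv1D (kernel 3, causal padding) → ReLU → layer
normalization.  The plain CNN pools with global averaging and classifies
with a softmax head; the hybrid variant replaces pooling with an LSTM over
the convolutional features (hidden size 250 for ``srad``, 300 for ``e4l``,
200 otherwise; dropout 0.4 for ``srad``, 0.5 otherwise).

Fusion profiles use early fusion: the constituent devices' channels are
resampled to a common rate and stacked as input channels of a single stack
whose block list is the deeper of the constituents.

Training is deterministic given :attr:`TrainingOptions.seed`: the split,
weight initialization, mini-batch shuffling, and dropout masks all derive
from it.  The final classification layer is zero-initialized, which makes
the whole training procedure exactly equivariant under a relabelling of the
classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from drivestress import engine
from drivestress.errors import EmptyInputError, InvalidSpecError
from drivestress.signals import SegmentSet

__all__ = [
    "ConvBlockSpec",
    "NetworkSpec",
    "TrainingOptions",
    "FittedModel",
    "PROFILES",
    "build_cnn",
    "build_cnn_lstm",
    "default_training_options",
    "count_parameters",
    "train",
    "predict",
    "predict_proba",
]

#: Per-profile convolutional front ends: (block filter list, trailing filters).
PROFILES = {
    "srad": ((8, 32, 64, 128), 8),
    "e4l": ((8, 32, 64, 128), 8),
    "e4r": ((8, 32, 64, 128), 8),
    "e4lr": ((8, 32, 64, 128), 8),
    "bh": ((128, 64, 32), None),
    "bh_e4lr": ((8, 32, 64, 128), 8),
}

#: Hybrid-model LSTM hidden sizes and dropout fractions per profile.
_LSTM_HIDDEN = {"srad": 250, "e4l": 300, "e4r": 200, "e4lr": 200, "bh": 200, "bh_e4lr": 200}
_LSTM_DROPOUT = {"srad": 0.4}  # all other profiles use 0.5

#: Effective (epochs, mini-batch) defaults per profile.
_TRAIN_DEFAULTS = {"srad": (20, 30)}  # all other profiles use (30, 20)


def _normalize_profile(profile: str) -> str:
    key = profile.lower().replace("-", "_").replace("+", "_").replace("(", "").replace(")", "")
    key = {"e4_l": "e4l", "e4_r": "e4r", "e4_l_r": "e4lr", "bh_e4_l_r": "bh_e4lr"}.get(key, key)
    if key not in PROFILES:
        raise InvalidSpecError(f"unknown device profile {profile!r}; expected one of {sorted(PROFILES)}")
    return key


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: Conv1D → ReLU → layer normalization."""

    filters: int
    kernel: int = 3
    padding: str = "causal"

    def __post_init__(self):
        if self.filters < 1 or self.kernel < 1:
            raise InvalidSpecError("filters and kernel must be >= 1")
        if self.padding != "causal":
            raise InvalidSpecError("only causal padding is supported")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative architecture: conv front end plus classification head.

    ``lstm_hidden`` and ``dropout`` are present together (hybrid CNN-LSTM)
    or both absent (plain CNN with global average pooling).
    """

    blocks: tuple
    trailing_conv: int | None
    n_classes: int
    lstm_hidden: int | None = None
    dropout: float | None = None
    pool: str = "gap"
    ln_axis: str = "features"
    profile: str = ""

    def __post_init__(self):
        if self.n_classes not in (2, 3):
            raise InvalidSpecError("n_classes must be 2 or 3")
        if (self.lstm_hidden is None) != (self.dropout is None):
            raise InvalidSpecError("lstm_hidden and dropout must be given together")
        if self.lstm_hidden is not None and self.lstm_hidden < 1:
            raise InvalidSpecError("lstm_hidden must be positive")

    @property
    def is_hybrid(self) -> bool:
        return self.lstm_hidden is not None

    @property
    def feature_channels(self) -> int:
        """Channel count leaving the convolutional front end."""
        return self.trailing_conv if self.trailing_conv else self.blocks[-1].filters

    def to_dict(self) -> dict:
        return {
            "blocks": [b.filters for b in self.blocks],
            "kernel": self.blocks[0].kernel,
            "trailing_conv": self.trailing_conv,
            "n_classes": self.n_classes,
            "lstm_hidden": self.lstm_hidden,
            "dropout": self.dropout,
            "pool": self.pool,
            "ln_axis": self.ln_axis,
            "profile": self.profile,
        }


@dataclass
class TrainingOptions:
    """Adam training hyper-parameters; all randomness flows from ``seed``."""

    epochs: int = 30
    minibatch: int = 20
    validation_frequency: int = 10
    split: float = 0.8
    seed: int = 0
    learning_rate: float = 1e-3
    optimizer: str = "adam"

    def __post_init__(self):
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")
        if self.epochs < 1 or self.minibatch < 1:
            raise ValueError("epochs and minibatch must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class FittedModel:
    """A trained network plus everything needed to audit or reuse it."""

    spec: NetworkSpec
    model: engine.Sequential
    in_channels: int
    class_names: tuple
    history: list
    train_idx: np.ndarray
    val_idx: np.ndarray
    opts: TrainingOptions

    @property
    def final_val_accuracy(self) -> float:
        return self.history[-1]["val_accuracy"]


def build_cnn(profile: str, n_classes: int, ln_axis: str = "features") -> NetworkSpec:
    """Table-driven plain 1D CNN spec for a device profile."""
    key = _normalize_profile(profile)
    filters, trailing = PROFILES[key]
    return NetworkSpec(
        blocks=tuple(ConvBlockSpec(f) for f in filters),
        trailing_conv=trailing,
        n_classes=n_classes,
        ln_axis=ln_axis,
        profile=key,
    )


def build_cnn_lstm(profile: str, n_classes: int, ln_axis: str = "features") -> NetworkSpec:
    """Hybrid 1D CNN-LSTM spec: CNN front end, then LSTM, dropout, softmax head."""
    key = _normalize_profile(profile)
    filters, trailing = PROFILES[key]
    return NetworkSpec(
        blocks=tuple(ConvBlockSpec(f) for f in filters),
        trailing_conv=trailing,
        n_classes=n_classes,
        lstm_hidden=_LSTM_HIDDEN[key],
        dropout=_LSTM_DROPOUT.get(key, 0.5),
        ln_axis=ln_axis,
        profile=key,
    )


def default_training_options(profile: str, seed: int = 0) -> TrainingOptions:
    """Effective (epochs, mini-batch) defaults: (20, 30) for srad, (30, 20) otherwise."""
    epochs, minibatch = _TRAIN_DEFAULTS.get(_normalize_profile(profile), (30, 20))
    return TrainingOptions(epochs=epochs, minibatch=minibatch, seed=seed)


def _build_model(spec: NetworkSpec, in_channels: int, rng: np.random.Generator,
                 dropout_rng: np.random.Generator | None = None) -> engine.Sequential:
    layers: list[engine.Layer] = []
    cin = in_channels
    for block in spec.blocks:
        layers.append(engine.Conv1D(cin, block.filters, block.kernel, rng))
        layers.append(engine.ReLU())
        layers.append(engine.LayerNorm(block.filters, axis=spec.ln_axis))
        cin = block.filters
    if spec.trailing_conv:
        layers.append(engine.Conv1D(cin, spec.trailing_conv, spec.blocks[0].kernel, rng))
        cin = spec.trailing_conv
    if spec.is_hybrid:
        layers.append(engine.LSTM(cin, spec.lstm_hidden, rng))
        layers.append(engine.Dropout(spec.dropout, dropout_rng or rng))
        cin = spec.lstm_hidden
    else:
        layers.append(engine.GlobalAveragePool())
    layers.append(engine.Dense(cin, spec.n_classes, rng, zero_init=True))
    return engine.Sequential(layers)


def count_parameters(spec: NetworkSpec, in_channels: int) -> int:
    """Exact trainable-parameter count of the realized network."""
    rng = np.random.default_rng(0)
    return _build_model(spec, in_channels, rng).n_parameters()


def _stratified_split(labels: np.ndarray, split: float, rng: np.random.Generator):
    """Deterministic stratified split.

    Indices are shuffled once, independent of the labels, and each class then
    contributes its leading shuffled members to the training side.  Because
    the shuffle ignores label values, relabelling classes leaves the selected
    index sets unchanged.
    """
    order = rng.permutation(len(labels))
    train, val = [], []
    for c in np.unique(labels):
        members = order[labels[order] == c]
        n_train = max(1, int(round(split * len(members))))
        if n_train == len(members) and len(members) > 1:
            n_train -= 1
        train.extend(members[:n_train])
        val.extend(members[n_train:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(val, dtype=int))


def _evaluate(model: engine.Sequential, x: np.ndarray, y: np.ndarray):
    logits = model.forward(x, train=False)
    loss, _, probs = engine.softmax_cross_entropy(logits, y)
    acc = float((probs.argmax(axis=1) == y).mean())
    return float(loss), acc


def train(spec: NetworkSpec, data: SegmentSet, opts: TrainingOptions) -> FittedModel:
    """Train a network on labelled windows; reproducible given ``opts.seed``."""
    if len(data) == 0:
        raise EmptyInputError("cannot train on an empty segment set")
    present = np.unique(data.labels)
    if len(present) == 1 and spec.n_classes > 1:
        warnings.warn(
            f"training data contains a single class ({data.class_names[present[0]]}); "
            "the model will collapse to the majority class",
            stacklevel=2,
        )
    if data.labels.max() >= spec.n_classes:
        raise ValueError("labels exceed the network's class count")

    ss = np.random.SeedSequence([int(opts.seed) & 0x7FFFFFFF])
    split_rng, init_rng, shuffle_rng, dropout_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    train_idx, val_idx = _stratified_split(data.labels, opts.split, split_rng)
    if opts.minibatch > len(train_idx):
        raise ValueError(
            f"minibatch {opts.minibatch} exceeds the training split size {len(train_idx)}"
        )

    model = _build_model(spec, data.n_channels, init_rng, dropout_rng)
    optimizer = engine.Adam(model.params, lr=opts.learning_rate)

    x_train, y_train = data.windows[train_idx], data.labels[train_idx]
    if len(val_idx):
        x_val, y_val = data.windows[val_idx], data.labels[val_idx]
    else:  # degenerate tiny sets: validate on the training data
        x_val, y_val = x_train, y_train

    history: list[dict] = []
    iteration = 0
    for _epoch in range(opts.epochs):
        perm = shuffle_rng.permutation(len(train_idx))
        for start in range(0, len(perm) - opts.minibatch + 1, opts.minibatch):
            batch = perm[start : start + opts.minibatch]
            logits = model.forward(x_train[batch], train=True)
            loss, dlogits, _ = engine.softmax_cross_entropy(logits, y_train[batch])
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step(model.grads)
            iteration += 1
            if iteration % opts.validation_frequency == 0:
                val_loss, val_acc = _evaluate(model, x_val, y_val)
                history.append(
                    {
                        "iteration": iteration,
                        "train_loss": float(loss),
                        "val_loss": val_loss,
                        "val_accuracy": val_acc,
                    }
                )
    val_loss, val_acc = _evaluate(model, x_val, y_val)
    history.append(
        {"iteration": iteration, "train_loss": None, "val_loss": val_loss, "val_accuracy": val_acc}
    )

    return FittedModel(
        spec=spec,
        model=model,
        in_channels=data.n_channels,
        class_names=data.class_names,
        history=history,
        train_idx=train_idx,
        val_idx=val_idx,
        opts=opts,
    )


def predict_proba(fitted: FittedModel, data: SegmentSet, batch: int = 256) -> np.ndarray:
    """Class probabilities per window; rows sum to one."""
    if len(data) == 0:
        return np.zeros((0, fitted.spec.n_classes))
    if data.n_channels != fitted.in_channels:
        raise ValueError(
            f"window channel count {data.n_channels} does not match the model's "
            f"input contract ({fitted.in_channels})"
        )
    out = []
    for start in range(0, len(data), batch):
        logits = fitted.model.forward(data.windows[start : start + batch], train=False)
        out.append(engine.softmax(logits))
    return np.concatenate(out)


def predict(fitted: FittedModel, data: SegmentSet) -> np.ndarray:
    """Most probable stress label per window."""
    probs = predict_proba(fitted, data)
    return probs.argmax(axis=1) if len(probs) else np.zeros(0, dtype=int)
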