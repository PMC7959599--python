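"""The three classifier architectures and their training regime.

* CNN — three width-5 1D convolution layers, each followed by a max-pool of
  size 4 with stride 1, then three fully connected layers of 1,025, 512 and
  128 ReLU units with 20% dropout, and a task head (1 sigmoid unit for
  binary, softmax over classes for multiclass).
* LSTM — a 128-unit LSTM whose final state feeds a 64-unit ReLU dense
  layer, 50% dropout, and the same task head.
* RF — a 300-tree random forest (min_samples_split=2, bootstrap off)
  consuming the flat integer token vectors as its feature table.

Neural models train for up to 10 epochs with batch size 128 under Adam at
the default 0.001 step size, with early stopping monitored on validation
loss. FBT token inputs pass through a learned embedding; one-hot inputs
enter the first convolution directly as 4**k channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .encoding import EncodedDataset
from .nn import (
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    Flatten,
    LSTM,
    MaxPool1D,
    ReLU,
    Sequential,
)

__all__ = [
    "CNNSpec",
    "LSTMSpec",
    "RFSpec",
    "TrainConfig",
    "InputContract",
    "TrainedModel",
    "build_cnn",
    "build_lstm",
    "build_rf",
    "train",
    "predict",
]


@dataclass(frozen=True)
class CNNSpec:
    n_conv_layers: int = 3
    filter_width: int = 5
    n_filters_per_layer: int = 64
    pool_size: int = 4
    pool_stride: int = 1
    dense_units: tuple[int, ...] = (1025, 512, 128)
    dropout_rate: float = 0.20
    embedding_dim: int = 32

    def __post_init__(self) -> None:
        if list(self.dense_units) != sorted(self.dense_units, reverse=True):
            raise ValueError("dense_units must be strictly decreasing")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in (0, 1)")


@dataclass(frozen=True)
class LSTMSpec:
    lstm_units: int = 128
    dense_units: int = 64
    dropout_rate: float = 0.50
    embedding_dim: int = 32


@dataclass(frozen=True)
class RFSpec:
    n_trees: int = 300
    min_samples_split: int = 2
    bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int | None = 2
    seed: int = 0


@dataclass(frozen=True)
class InputContract:
    """What a trained model will accept at predict time."""

    encoder: str
    k: int
    source_length: int
    vocab_checksum: str
    n_classes: int

    def check(self, data: EncodedDataset) -> None:
        problems = []
        if data.encoder != self.encoder:
            problems.append(f"encoder {data.encoder!r} != {self.encoder!r}")
        if data.k != self.k:
            problems.append(f"k {data.k} != {self.k}")
        if data.source_length != self.source_length:
            problems.append(
                f"sequence length {data.source_length} != {self.source_length}"
            )
        if self.encoder == "fbt" and data.vocab_checksum != self.vocab_checksum:
            problems.append(
                f"vocabulary checksum {data.vocab_checksum} != {self.vocab_checksum}"
            )
        if problems:
            raise ValueError(
                "encoded input violates the model's input contract: "
                + "; ".join(problems)
            )


@dataclass
class TrainedModel:
    kind: str  # cnn | lstm | rf
    estimator: Any  # Sequential or fitted RandomForestClassifier
    contract: InputContract
    history: Any = None  # TrainingHistory for neural models
    spec: Any = None


def _head_units(n_classes: int) -> int:
    return 1 if n_classes == 2 else n_classes


def _loss_for(n_classes: int) -> str:
    return "bce" if n_classes == 2 else "sce"


def _front_layers(encoder, embedding_dim, vocab_size, rng):
    """Embedding lookup for token input; raw channels for one-hot."""
    if encoder == "fbt":
        return [Embedding(vocab_size, embedding_dim, rng)], embedding_dim
    return [], vocab_size  # one-hot: 4**k input channels


def build_cnn(
    spec: CNNSpec,
    vocab_size: int,
    n_positions: int,
    n_classes: int = 2,
    encoder: str = "fbt",
    seed: int = 0,
) -> Sequential:
    """Untrained CNN for ``n_positions``-long encoded sequences."""
    if n_positions < spec.filter_width:
        raise ValueError(
            f"n_positions={n_positions} shorter than filter width {spec.filter_width}"
        )
    rng = np.random.default_rng(seed)
    layers, c_in = _front_layers(encoder, spec.embedding_dim, vocab_size, rng)
    T = n_positions
    for _ in range(spec.n_conv_layers):
        layers += [
            Conv1D(c_in, spec.n_filters_per_layer, spec.filter_width, rng),
            ReLU(),
            MaxPool1D(spec.pool_size, spec.pool_stride),
        ]
        c_in = spec.n_filters_per_layer
        T = (T - spec.pool_size) // spec.pool_stride + 1
    layers.append(Flatten())
    n_in = c_in * T
    for units in spec.dense_units:
        layers += [Dense(n_in, units, rng), ReLU(), Dropout(spec.dropout_rate)]
        n_in = units
    layers.append(Dense(n_in, _head_units(n_classes), rng))
    return Sequential(layers, loss=_loss_for(n_classes))


def build_lstm(
    spec: LSTMSpec,
    vocab_size: int,
    n_positions: int,
    n_classes: int = 2,
    encoder: str = "fbt",
    seed: int = 0,
) -> Sequential:
    """Untrained LSTM network; the final hidden state feeds the dense head."""
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    rng = np.random.default_rng(seed)
    layers, d_in = _front_layers(encoder, spec.embedding_dim, vocab_size, rng)
    layers += [
        LSTM(d_in, spec.lstm_units, rng),
        Dense(spec.lstm_units, spec.dense_units, rng),
        ReLU(),
        Dropout(spec.dropout_rate),
        Dense(spec.dense_units, _head_units(n_classes), rng),
    ]
    return Sequential(layers, loss=_loss_for(n_classes))


def build_rf(spec: RFSpec, seed: int = 0) -> RandomForestClassifier:
    """Random forest over flat token vectors."""
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        min_samples_split=spec.min_samples_split,
        bootstrap=spec.bootstrap,
        random_state=seed,
        n_jobs=1,
    )


def _as_float_input(data: EncodedDataset) -> np.ndarray:
    if data.encoder == "fbt":
        return data.X  # integer tokens for the embedding layer
    return data.X.astype(np.float32)


def train(
    model: Sequential | RandomForestClassifier,
    data: EncodedDataset,
    val_data: EncodedDataset | None,
    config: TrainConfig,
    kind: str | None = None,
    spec: Any = None,
    n_classes: int | None = None,
) -> TrainedModel:
    """Fit a built model on an encoded training set.

    Neural models run at most ``config.epochs`` epochs of batch
    ``config.batch_size`` Adam updates with early stopping on validation
    loss; the forest ignores the epoch schedule. Labels must lie in
    ``[0, n_classes)``.
    """
    if n_classes is None:
        n_classes = int(max(data.y.max(), 1)) + 1 if data.y.max() > 1 else 2
    if data.y.min() < 0 or data.y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    contract = InputContract(
        encoder=data.encoder,
        k=data.k,
        source_length=data.source_length,
        vocab_checksum=data.vocab_checksum,
        n_classes=n_classes,
    )
    if isinstance(model, RandomForestClassifier):
        if data.encoder != "fbt":
            raise ValueError("the random forest consumes FBT token vectors")
        model.fit(data.X, data.y)
        return TrainedModel(
            kind=kind or "rf", estimator=model, contract=contract, spec=spec
        )
    if val_data is not None:
        contract.check(val_data)
        val_X, val_y = _as_float_input(val_data), val_data.y
    else:
        val_X = val_y = None
    history = model.fit(
        _as_float_input(data),
        data.y,
        val_X,
        val_y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        patience=config.patience,
        seed=config.seed,
    )
    return TrainedModel(
        kind=kind or "nn",
        estimator=model,
        contract=contract,
        history=history,
        spec=spec,
    )


def predict(
    model: TrainedModel, data: EncodedDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample class probabilities and hard labels.

    Binary: label 1 iff P(promoter) >= 0.5. Multiclass: argmax, ties toward
    the smaller class index. Refuses inputs that violate the model's input
    contract (wrong encoder, k, length or vocabulary).
    """
    model.contract.check(data)
    if isinstance(model.estimator, RandomForestClassifier):
        proba = model.estimator.predict_proba(data.X)
        classes = model.estimator.classes_
        if model.contract.n_classes == 2:
            pos_col = np.where(classes == 1)[0]
            p1 = proba[:, pos_col[0]] if len(pos_col) else np.zeros(len(data.X))
            return p1, (p1 >= 0.5).astype(np.int64)
        full = np.zeros((len(data.X), model.contract.n_classes))
        full[:, classes] = proba
        return full, full.argmax(axis=1)
    proba = model.estimator.predict_proba(_as_float_input(data))
    if model.contract.n_classes == 2:
        return proba, (proba >= 0.5).astype(np.int64)
    return proba, proba.argmax(axis=1)
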