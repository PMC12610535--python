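"""Training harness for the stress classifiers.

The primary model is a single-layer LSTM with 144 units (tanh cell,
sigmoid gates), input dropout 0.2, batch normalization on the last hidden
state, an intermediate dense layer of 36 units and a 3-way softmax,
optimized with Adam (lr 1e-3), batch size 36, up to 100 epochs with early
stopping on validation macro-F1 and reduce-on-plateau. A ReLU variant
adds gradient clipping (clipnorm 1.0) and recurrent dropout 0.1 to keep
the unbounded cell state stable.

Baselines cover the usual tabular families (logistic regression, random
forest with 200 trees, RBF-SVM with C=1 and gamma='scale', k-NN, one- and
two-layer dense networks, optional XGBoost) on flattened windows, plus
lightweight sequence models (1-D CNN with global average pooling, GRU
with 16 units, stacked LSTM 32 -> 16). Every family trains with or
without the FFT-derived circadian channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .nn import (
    Adam,
    BatchNorm,
    Conv1DGap,
    Dense,
    Dropout,
    GRU,
    LSTM,
    ReLU,
    Sequential,
    SoftmaxCrossEntropy,
    softmax,
)
from .sequences import BEHAVIOR_CHANNELS, ChannelScaler, SequenceData

__all__ = [
    "ModelConfig",
    "relu_variant",
    "TrainedModel",
    "train_lstm",
    "train_baseline",
    "predict",
    "BASELINE_TAGS",
]

BASELINE_TAGS = (
    "logreg", "rf", "svm", "knn", "xgboost",
    "cnn1d", "gru16", "lstm_32_16", "ann", "dnn",
)

_N_CLASSES = 3


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "lstm"
    lstm_units: int = 144
    dense_units: int = 36
    dropout: float = 0.2
    recurrent_dropout: float = 0.0
    activation: str = "tanh"
    recurrent_activation: str = "sigmoid"
    batch_norm: bool = True
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 36
    clipnorm: float | None = None
    early_stopping_patience: int = 8
    reduce_lr_patience: int = 4
    reduce_lr_factor: float = 0.5
    min_lr: float = 1e-5
    val_fraction: float = 0.15  # chronological tail per cow
    class_weight: str | None = None  # None or "balanced" (inverse frequency)
    track_train_f1: bool = False  # record per-epoch training macro-F1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation == "relu" and self.clipnorm is None:
            raise ValueError("the relu variant requires gradient clipping (clipnorm)")


def relu_variant(base: ModelConfig | None = None, **overrides) -> ModelConfig:
    """The ReLU cell variant: clipnorm 1.0 and recurrent dropout 0.1."""
    base = base or ModelConfig()
    return replace(
        base, activation="relu", clipnorm=1.0, recurrent_dropout=0.1, **overrides
    )


@dataclass
class TrainedModel:
    kind: str                     # "sequence" or "tabular"
    tag: str
    scaler: ChannelScaler
    channels: list[str]
    net: Sequential | None = None
    sk_model: object | None = None
    history: dict | None = None
    classes_present: np.ndarray | None = None


def _chronological_val_split(data: SequenceData, fraction: float):
    """Last ``fraction`` of each cow's samples (by anchor time) validate."""
    val_mask = np.zeros(len(data), dtype=bool)
    for cow in np.unique(data.cow_ids):
        idx = np.flatnonzero(data.cow_ids == cow)
        idx = idx[np.argsort(data.anchors[idx])]
        n_val = max(1, int(round(fraction * len(idx))))
        val_mask[idx[-n_val:]] = True
    return ~val_mask, val_mask


def _onehot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), _N_CLASSES))
    out[np.arange(len(y)), y] = 1.0
    return out


def _build_lstm(n_channels: int, config: ModelConfig, rng) -> Sequential:
    layers = [
        LSTM(
            n_channels,
            config.lstm_units,
            rng,
            activation=config.activation,
            recurrent_activation=config.recurrent_activation,
            dropout=config.dropout,
            recurrent_dropout=config.recurrent_dropout,
        )
    ]
    if config.batch_norm:
        layers.append(BatchNorm(config.lstm_units))
    layers += [
        Dense(config.lstm_units, config.dense_units, rng),
        ReLU(),
        Dropout(config.dropout, rng),
        Dense(config.dense_units, _N_CLASSES, rng),
    ]
    return Sequential(layers)


def _fit_net(
    net: Sequential,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig,
    rng,
) -> dict:
    """Adam + early stopping on validation macro-F1 + reduce-on-plateau."""
    opt = Adam(lr=config.learning_rate, clipnorm=config.clipnorm)
    lossfn = SoftmaxCrossEntropy()
    y1h = _onehot(y_tr)
    n = len(X_tr)
    weights = None
    if config.class_weight == "balanced":
        counts = np.bincount(y_tr, minlength=_N_CLASSES).astype(float)
        per_class = np.where(counts > 0, n / (np.count_nonzero(counts) * counts), 0.0)
        weights = per_class[y_tr]
    best_f1, best_weights, best_epoch = -np.inf, net.get_weights(), -1
    since_best, since_reduce = 0, 0
    history = {"loss": [], "val_macro_f1": [], "lr": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, config.batch_size):
            sel = order[lo : lo + config.batch_size]
            logits = net.forward(X_tr[sel], training=True)
            loss, dlogits = lossfn.loss_and_grad(
                logits, y1h[sel], None if weights is None else weights[sel]
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            net.backward(dlogits)
            opt.step(net.params, net.grads)
            total += loss * len(sel)
        val_pred = np.argmax(net.forward(X_val, training=False), axis=1)
        f1 = f1_score(y_val, val_pred, average="macro", zero_division=0)
        if config.track_train_f1:
            tr_pred = np.argmax(net.forward(X_tr, training=False), axis=1)
            history.setdefault("train_macro_f1", []).append(
                float(f1_score(y_tr, tr_pred, average="macro", zero_division=0))
            )
        history["loss"].append(total / n)
        history["val_macro_f1"].append(float(f1))
        history["lr"].append(opt.lr)
        if f1 > best_f1 + 1e-6:
            best_f1, best_weights, best_epoch = f1, net.get_weights(), epoch
            since_best = since_reduce = 0
        else:
            since_best += 1
            since_reduce += 1
            if since_reduce >= config.reduce_lr_patience and opt.lr > config.min_lr:
                opt.lr = max(opt.lr * config.reduce_lr_factor, config.min_lr)
                since_reduce = 0
            if since_best >= config.early_stopping_patience:
                break
    net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_macro_f1"] = float(best_f1)
    return history


def train_lstm(data: SequenceData, config: ModelConfig | None = None) -> TrainedModel:
    """Train the primary LSTM classifier (deterministic given the seed)."""
    config = config or ModelConfig()
    if len(np.unique(data.y)) < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(config.seed)
    tr_mask, val_mask = _chronological_val_split(data, config.val_fraction)
    scaler = ChannelScaler().fit(data.X[tr_mask])
    X_tr, X_val = scaler.transform(data.X[tr_mask]), scaler.transform(data.X[val_mask])
    net = _build_lstm(data.X.shape[2], config, rng)
    history = _fit_net(net, X_tr, data.y[tr_mask], X_val, data.y[val_mask], config, rng)
    return TrainedModel(
        kind="sequence", tag="lstm", scaler=scaler, channels=list(data.channels),
        net=net, history=history,
    )


def _flatten(X: np.ndarray) -> np.ndarray:
    return X.reshape(len(X), -1)


def _make_tabular(tag: str, seed: int, class_weight=None):
    if tag == "logreg":
        return LogisticRegression(max_iter=2000, class_weight=class_weight)
    if tag == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed, class_weight=class_weight)
    if tag == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", probability=True, random_state=seed, class_weight=class_weight)
    if tag == "knn":
        return KNeighborsClassifier()
    if tag == "ann":
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=400, random_state=seed)
    if tag == "dnn":
        return MLPClassifier(hidden_layer_sizes=(64, 32), max_iter=400, random_state=seed)
    if tag == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError:
            warnings.warn("xgboost is not installed; skipping this baseline")
            return None
        return XGBClassifier(
            n_estimators=200, random_state=seed, objective="multi:softprob",
            num_class=_N_CLASSES,
        )
    raise ValueError(f"unknown baseline tag {tag!r}")


def _strip_fft(data: SequenceData) -> SequenceData:
    keep = [i for i, c in enumerate(data.channels) if c in BEHAVIOR_CHANNELS]
    return SequenceData(
        X=data.X[:, :, keep], y=data.y, cow_ids=data.cow_ids, anchors=data.anchors,
        channels=[data.channels[i] for i in keep], horizon=data.horizon,
    )


def train_baseline(
    data: SequenceData,
    which: str,
    with_fft: bool = True,
    config: ModelConfig | None = None,
) -> TrainedModel | None:
    """Train one baseline family; ``with_fft=False`` drops the spectral channels."""
    if which not in BASELINE_TAGS:
        raise ValueError(f"unknown baseline tag {which!r}; choose from {BASELINE_TAGS}")
    config = config or ModelConfig()
    if not with_fft:
        data = _strip_fft(data)
    if len(np.unique(data.y)) < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(config.seed)

    if which in ("cnn1d", "gru16", "lstm_32_16"):
        tr_mask, val_mask = _chronological_val_split(data, config.val_fraction)
        scaler = ChannelScaler().fit(data.X[tr_mask])
        X_tr, X_val = scaler.transform(data.X[tr_mask]), scaler.transform(data.X[val_mask])
        D = data.X.shape[2]
        if which == "cnn1d":
            net = Sequential([Conv1DGap(D, 32, 3, rng), Dense(32, _N_CLASSES, rng)])
        elif which == "gru16":
            net = Sequential([GRU(D, 16, rng), Dense(16, _N_CLASSES, rng)])
        else:
            net = Sequential(
                [
                    LSTM(D, 32, rng, return_sequences=True),
                    LSTM(32, 16, rng),
                    Dense(16, _N_CLASSES, rng),
                ]
            )
        history = _fit_net(net, X_tr, data.y[tr_mask], X_val, data.y[val_mask], config, rng)
        return TrainedModel(
            kind="sequence", tag=which, scaler=scaler, channels=list(data.channels),
            net=net, history=history,
        )

    model = _make_tabular(which, config.seed, class_weight=config.class_weight)
    if model is None:
        return None
    scaler = ChannelScaler().fit(data.X)
    X = _flatten(scaler.transform(data.X))
    model.fit(X, data.y)
    return TrainedModel(
        kind="tabular", tag=which, scaler=scaler, channels=list(data.channels),
        sk_model=model, classes_present=np.unique(data.y),
    )


def predict(model: TrainedModel, data: SequenceData, mode: str = "contemporary"):
    """Class probabilities and hard labels for a sample collection.

    ``mode`` is a bookkeeping tag ("contemporary" for horizon-0 targets,
    "prospective" for one-hour-ahead targets). Ties in the probability
    vector break toward the lower severity class.
    """
    if list(data.channels) != list(model.channels):
        missing = set(model.channels) - set(data.channels)
        extra = set(data.channels) - set(model.channels)
        raise ValueError(
            f"feature schema mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    Xs = model.scaler.transform(data.X)
    if model.kind == "sequence":
        probs = softmax(model.net.forward(Xs, training=False))
    else:
        raw = model.sk_model.predict_proba(_flatten(Xs))
        probs = np.zeros((len(raw), _N_CLASSES))
        probs[:, model.classes_present] = raw
    labels = np.argmax(probs, axis=1)  # argmax returns the first (lowest) class on ties
    return {
        "probabilities": probs,
        "labels": labels,
        "mode": mode,
        "cow_ids": data.cow_ids,
        "anchors": data.anchors,
    }
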