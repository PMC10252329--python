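"""DeepConvLSTM backbone with optional attention blocks, training, counting.

The backbone is the standard sensor-HAR hybrid: a window of ``H`` time
steps by ``D`` signals passes through four temporal convolution layers
(64 filters, kernel spanning 5 samples along time and 1 along the signal
axis, valid padding, ReLU), the 64 feature maps are flattened per time
step (``64 * D`` features), fed to two LSTM layers with 128 units, and
the last time step's output drives a softmax over the classes.

Attention blocks (:class:`~cbamhar.attention.AttentionSpec`) are inserted
immediately after the ReLU of the conv layers they name; placement
``"all"`` inserts an independent block after every conv layer.

Training uses Adam (default parameters, learning rate 0.001), batch size
64 and categorical cross-entropy, with an optional
best-validation-macro-F1 checkpoint.  Everything is seeded: two builds
from the same config are bitwise identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .attention import AttentionSpec, ConfigurationError
from .data import WindowedDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "DeepConvLSTM",
    "build_model",
    "count_trainable_params",
    "backbone_param_count",
    "train",
    "predict_proba",
]


@dataclass(frozen=True)
class ModelConfig:
    """Backbone hyperparameters plus the attention blocks to insert.

    Canonical values are 4 conv layers x 64 filters and 2 LSTM layers x
    128 units; smaller values are accepted for quick experiments.  The
    window must survive ``n_conv_layers`` valid convolutions:
    ``window_length - n_conv_layers * (conv_kernel_time - 1) >= 1``.
    """

    window_length: int
    n_signals: int
    n_classes: int
    n_conv_layers: int = 4
    conv_filters: int = 64
    conv_kernel_time: int = 5
    lstm_units: int = 128
    n_lstm_layers: int = 2
    lstm_dropout: float = 0.0
    attention: tuple[AttentionSpec, ...] = ()
    seed: int = 0
    dtype: str = "float32"
    mlp_hidden_activation: str = "relu"

    def __post_init__(self):
        object.__setattr__(self, "attention", tuple(self.attention))
        if self.final_time_steps < 1:
            raise ConfigurationError(
                f"window of {self.window_length} samples is too short for "
                f"{self.n_conv_layers} valid convolutions of kernel "
                f"{self.conv_kernel_time}"
            )
        if not 0.0 <= self.lstm_dropout < 1.0:
            raise ConfigurationError("lstm_dropout must be in [0, 1)")
        for spec in self.attention:
            if spec.placement != "all" and spec.placement > self.n_conv_layers:
                raise ConfigurationError(
                    f"attention placement {spec.placement} exceeds "
                    f"{self.n_conv_layers} conv layers"
                )

    @property
    def final_time_steps(self) -> int:
        return self.window_length - self.n_conv_layers * (self.conv_kernel_time - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["attention"] = [
            dict(mode=s.mode, r=s.r, k=s.k, placement=s.placement)
            for s in self.attention
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["attention"] = tuple(AttentionSpec(**a) for a in d.get("attention", ()))
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Adam training schedule (defaults follow the common HAR setup)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 50
    patience: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


class DeepConvLSTM:
    """A built (trainable) network; create via :func:`build_model`."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        self.feature_layers: list[nn.Layer] = []
        self.attention_layers: list[nn.Layer] = []
        in_ch = 1
        for layer_idx in range(1, cfg.n_conv_layers + 1):
            self.feature_layers.append(
                nn.TemporalConv(in_ch, cfg.conv_filters, cfg.conv_kernel_time,
                                rng, dtype=dtype)
            )
            self.feature_layers.append(nn.ReLU())
            for spec in cfg.attention:
                if spec.placement == "all" or spec.placement == layer_idx:
                    if spec.uses_channel:
                        lay = nn.ChannelAttention(
                            cfg.conv_filters, spec.r, rng,
                            hidden_activation=cfg.mlp_hidden_activation, dtype=dtype)
                        self.feature_layers.append(lay)
                        self.attention_layers.append(lay)
                    if spec.uses_spatial:
                        lay = nn.SpatialAttention(spec.k, rng, dtype=dtype)
                        self.feature_layers.append(lay)
                        self.attention_layers.append(lay)
            in_ch = cfg.conv_filters
        n_feat = cfg.conv_filters * cfg.n_signals
        self.recurrent_layers: list[nn.Layer] = []
        drop_rng = np.random.default_rng(rng.integers(2**31))
        for i in range(cfg.n_lstm_layers):
            self.recurrent_layers.append(
                nn.LSTM(n_feat if i == 0 else cfg.lstm_units, cfg.lstm_units,
                        rng, dtype=dtype)
            )
            self.recurrent_layers.append(nn.Dropout(cfg.lstm_dropout, drop_rng))
        self.head = nn.Dense(cfg.lstm_units, cfg.n_classes, rng, dtype=dtype)
        self.dtype = dtype

    # -- forward / backward -------------------------------------------------

    def _to_feature_input(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1:] != (self.cfg.window_length, self.cfg.n_signals):
            raise ConfigurationError(
                f"windows must have shape (N, {self.cfg.window_length}, "
                f"{self.cfg.n_signals}), got {x.shape}"
            )
        return x[:, None, :, :]  # (N, 1, H, D)

    def conv_features(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        """Output of the (attention-refined) conv stack, ``(N, C, Ht, D)``."""
        x = self._to_feature_input(windows)
        for layer in self.feature_layers:
            x = layer.forward(x, train=train)
        return x

    def forward(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        """Class logits ``(N, n_classes)``."""
        x = self.conv_features(windows, train=train)
        n, c, ht, w = x.shape
        seq = np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, ht, c * w)
        for layer in self.recurrent_layers:
            seq = layer.forward(seq, train=train)
        self._seq_shape = seq.shape
        self._conv_shape = (n, c, ht, w)
        return self.head.forward(seq[:, -1, :], train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dlast = self.head.backward(dlogits)
        n, t, u = self._seq_shape
        dseq = np.zeros(self._seq_shape, dtype=dlast.dtype)
        dseq[:, -1, :] = dlast
        for layer in reversed(self.recurrent_layers):
            dseq = layer.backward(dseq)
        n, c, ht, w = self._conv_shape
        dx = np.ascontiguousarray(
            dseq.reshape(n, ht, c, w).transpose(0, 2, 1, 3)
        )
        for layer in reversed(self.feature_layers):
            dx = layer.backward(dx)

    def loss_and_grad(self, windows: np.ndarray, labels: np.ndarray,
                      train: bool = True) -> float:
        logits = self.forward(windows, train=train)
        loss, dlogits = nn.softmax_cross_entropy(logits, labels)
        self.backward(dlogits)
        return loss

    # -- inference ---------------------------------------------------------

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256
                      ) -> np.ndarray:
        out = []
        for i in range(0, len(windows), batch_size):
            logits = self.forward(windows[i:i + batch_size], train=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out) if out else np.empty((0, self.cfg.n_classes))

    def predict(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(windows, batch_size).argmax(axis=1)

    # -- parameters ---------------------------------------------------------

    def _all_layers(self) -> list[nn.Layer]:
        return [*self.feature_layers, *self.recurrent_layers, self.head]

    def parameters(self) -> list[np.ndarray]:
        return [p for lay in self._all_layers() for p in lay.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for lay in self._all_layers() for g in lay.grads()]

    def attention_parameters(self) -> list[np.ndarray]:
        return [p for lay in self.attention_layers for p in lay.params()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.cfg.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "DeepConvLSTM":
        path = Path(path)
        cfg = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as z:
            model.set_weights([z[f"p{i}"] for i in range(len(z.files))])
        return model


def build_model(cfg: ModelConfig) -> DeepConvLSTM:
    """Construct the network described by *cfg* (deterministic per seed)."""
    return DeepConvLSTM(cfg)


def count_trainable_params(model: DeepConvLSTM) -> int:
    """Exact number of trainable scalars in a built model."""
    return int(sum(p.size for p in model.parameters()))


def backbone_param_count(cfg: ModelConfig) -> int:
    """Closed-form parameter count of the attention-free backbone."""
    kt, f = cfg.conv_kernel_time, cfg.conv_filters
    total = f * kt + f  # first conv, 1 input channel
    total += (cfg.n_conv_layers - 1) * (f * f * kt + f)
    n_in = f * cfg.n_signals
    u = cfg.lstm_units
    for i in range(cfg.n_lstm_layers):
        total += 4 * u * ((n_in if i == 0 else u) + u) + 4 * u
    total += u * cfg.n_classes + cfg.n_classes
    return total


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    from .evaluation import macro_f1  # local import avoids a cycle at import time

    return macro_f1(y_true, y_pred, n_classes)


def train(model: DeepConvLSTM, data: WindowedDataset, tc: TrainConfig
          ) -> tuple[DeepConvLSTM, dict]:
    """Train on the dataset's ``train`` split (or all windows if unsplit).

    If a ``val`` split is present, validation macro-F1 is recorded per
    epoch and the best-scoring weights are restored at the end; with a
    ``patience`` the loop stops after that many epochs without
    improvement.  Returns the model and a history dict with per-epoch
    ``loss`` and ``val_macro_f1``.
    """
    if data.split is not None:
        train_ds = data.subset(split="train")
        val_ds = data.subset(split="val")
        has_val = len(val_ds.windows) > 0
    else:
        train_ds, val_ds, has_val = data, None, False
    x, y = train_ds.windows, train_ds.labels
    if len(x) == 0:
        raise ValueError("empty training split")
    history: dict = {"loss": [], "val_macro_f1": []}
    if tc.max_epochs == 0:
        return model, history

    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    best_score, best_weights, since_best = -np.inf, None, 0
    for _epoch in range(tc.max_epochs):
        order = rng.permutation(len(x))
        total, seen = 0.0, 0
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            loss = model.loss_and_grad(x[idx], y[idx], train=True)
            opt.step(model.gradients())
            total += loss * len(idx)
            seen += len(idx)
        history["loss"].append(total / seen)
        if has_val:
            score = _macro_f1(val_ds.labels, model.predict(val_ds.windows),
                              data.n_classes)
            history["val_macro_f1"].append(score)
            if score > best_score:
                best_score, best_weights, since_best = score, model.get_weights(), 0
            else:
                since_best += 1
                if tc.patience is not None and since_best >= tc.patience:
                    break
    if best_weights is not None:
        model.set_weights(best_weights)
    return model, history


def predict_proba(model: DeepConvLSTM, windows: np.ndarray) -> np.ndarray:
    """Per-window class probability vectors (rows sum to 1)."""
    return model.predict_proba(windows)
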