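"""The two head-map regressor architectures.

* A VGG-style CNN over a single 32x32x5 head-map tensor: three convolutional
  blocks of 3x3/stride-1 ReLU layers (4x32 filters, 2x64, 1x128), each block
  closed by 2x2/stride-2 max pooling.  In standalone mode a regression head
  (dense 512 ReLU -> dropout 0.5 -> dense 1 linear) predicts the next
  window's brain rate; in trunk mode the flattened feature vector is exposed
  (2048 = 4x4x128 under 'same' conv padding, 128 = 1x1x128 under 'valid').

* A convolutional-recurrent model for sequences of z tensors: the z frames
  pass through *one shared* CNN trunk (time-distributed, a single parameter
  set), the z feature vectors feed a single 128-unit LSTM whose last output
  is kept, and in parallel a 1D convolution (64 filters, valid padding) over
  the same feature sequence captures frame-to-frame variation.  Both are
  concatenated and regressed through dropout 0.5 -> dense 512 ReLU ->
  dropout 0.5 -> dense 1 linear.

The conv-padding policy and the LSTM peephole terms are configuration flags;
both change the trainable-parameter count, so the active flags and the exact
count are recorded in each model's manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Conv1D, Conv2D, Dense, Dropout, Flatten, LSTM, Layer,
                 MaxPool2D, ReLU, Sequential)

__all__ = ["CNNSpec", "LSTMLayerSpec", "FullModelSpec", "CNNRegressor",
           "CNNLSTMRegressor", "build_cnn", "build_full_model", "count_parameters"]

INPUT_SHAPE = (32, 32, 5)


@dataclass(frozen=True)
class CNNSpec:
    """Declarative description of the VGG-style CNN."""

    input_shape: tuple[int, int, int] = INPUT_SHAPE
    blocks: tuple[tuple[int, int], ...] = ((32, 4), (64, 2), (128, 1))  # (filters, n_layers)
    kernel: int = 3
    padding: str = "same"  # one policy flag shared by all conv layers
    dense_units: int = 512
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.padding not in ("same", "valid"):
            raise ValueError(f"unknown padding policy {self.padding!r}")

    def feature_length(self) -> int:
        """Flattened trunk output length implied by the padding policy."""
        h = self.input_shape[0]
        for _, n_layers in self.blocks:
            if self.padding == "valid":
                h -= (self.kernel - 1) * n_layers
            if h < 1:
                raise ValueError("padding policy collapses the spatial extent below 1")
            h = (h + 1) // 2  # 2x2 pool, stride 2, 'same'
        return h * h * self.blocks[-1][0]


@dataclass(frozen=True)
class LSTMLayerSpec:
    """One LSTM layer; peephole toggles the cell-state terms in the gates."""

    units: int = 128
    layers: int = 1
    peephole: bool = False

    def __post_init__(self) -> None:
        if self.units < 1 or self.layers != 1:
            raise ValueError("a single LSTM layer with >= 1 units is required")


@dataclass(frozen=True)
class FullModelSpec:
    """The z-branch shared-weight CNN + LSTM architecture."""

    z: int = 7
    cnn: CNNSpec = field(default_factory=CNNSpec)
    lstm: LSTMLayerSpec = field(default_factory=LSTMLayerSpec)
    side_filters: int = 64
    side_kernel: int = 3
    dense_units: int = 512
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("sequence length z must be >= 1")


def _trunk(spec: CNNSpec, rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = []
    in_ch = spec.input_shape[2]
    for filters, n_layers in spec.blocks:
        for _ in range(n_layers):
            layers += [Conv2D(in_ch, filters, spec.kernel, spec.padding, rng), ReLU()]
            in_ch = filters
        layers.append(MaxPool2D(2))
    layers.append(Flatten())
    return Sequential(layers)


class CNNRegressor:
    """Standalone CNN: one head-map tensor in, one brain-rate scalar out."""

    def __init__(self, spec: CNNSpec = CNNSpec(), seed: int | None = None) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.trunk = _trunk(spec, rng)
        feat = spec.feature_length()
        self.head = Sequential([
            Dense(feat, spec.dense_units, rng), ReLU(),
            Dropout(spec.dropout, np.random.default_rng(rng.integers(2**31))),
            Dense(spec.dense_units, 1, rng),
        ])
        self._net = Sequential([self.trunk, self.head])

    @property
    def params(self) -> list[np.ndarray]:
        return self._net.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self._net.grads

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """[N, 32, 32, 5] (or [N, 1, 32, 32, 5]) -> [N] predictions."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 5:
            if x.shape[1] != 1:
                raise ValueError("CNNRegressor takes single frames; got a sequence")
            x = x[:, 0]
        return self._net.forward(x, training=training)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        self._net.backward(np.asarray(dy, dtype=np.float32)[:, None])

    def manifest(self) -> dict:
        return {
            "architecture": "cnn",
            "padding": self.spec.padding,
            "blocks": list(self.spec.blocks),
            "feature_length": self.spec.feature_length(),
            "n_parameters": count_parameters(self),
        }


class CNNLSTMRegressor:
    """Shared-trunk convolutional-recurrent regressor over z-frame sequences."""

    def __init__(self, spec: FullModelSpec = FullModelSpec(), seed: int | None = None) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.trunk = _trunk(spec.cnn, rng)  # one parameter set shared by all z branches
        feat = spec.cnn.feature_length()
        self.side_kernel = min(spec.side_kernel, spec.z)
        self.side = Sequential([Conv1D(feat, spec.side_filters, self.side_kernel, rng), ReLU(), Flatten()])
        self.lstm = LSTM(feat, spec.lstm.units, peephole=spec.lstm.peephole, rng=rng)
        side_len = (spec.z - self.side_kernel + 1) * spec.side_filters
        drop_rng = np.random.default_rng(rng.integers(2**31))
        self.head = Sequential([
            Dropout(spec.dropout, drop_rng),
            Dense(side_len + spec.lstm.units, spec.dense_units, rng), ReLU(),
            Dropout(spec.dropout, drop_rng),
            Dense(spec.dense_units, 1, rng),
        ])
        self._feat = feat

    @property
    def params(self) -> list[np.ndarray]:
        return self.trunk.params + self.lstm.params + self.side.params + self.head.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.trunk.grads + self.lstm.grads + self.side.grads + self.head.grads

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """[N, z, 32, 32, 5] -> [N] predictions."""
        x = np.asarray(x, dtype=np.float32)
        N, z = x.shape[:2]
        if z != self.spec.z:
            raise ValueError(f"model built for z={self.spec.z}, got sequences of length {z}")
        frames = x.reshape(N * z, *x.shape[2:])
        feats = self.trunk.forward(frames, training=training).reshape(N, z, self._feat)
        self._shape = (N, z)
        h_last = self.lstm.forward(feats, training=training)
        side_out = self.side.forward(feats, training=training)
        merged = np.concatenate([side_out, h_last], axis=1)
        self._side_len = side_out.shape[1]
        return self.head.forward(merged, training=training)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        N, z = self._shape
        dmerged = self.head.backward(np.asarray(dy, dtype=np.float32)[:, None])
        dside, dh = dmerged[:, : self._side_len], dmerged[:, self._side_len :]
        dfeats = self.side.backward(dside) + self.lstm.backward(dh)
        self.trunk.backward(dfeats.reshape(N * z, self._feat))

    def manifest(self) -> dict:
        return {
            "architecture": "cnn_lstm",
            "z": self.spec.z,
            "padding": self.spec.cnn.padding,
            "lstm_units": self.spec.lstm.units,
            "peephole": self.spec.lstm.peephole,
            "side_filters": self.spec.side_filters,
            "side_kernel": self.side_kernel,
            "feature_length": self._feat,
            "n_parameters": count_parameters(self),
        }


def build_cnn(spec: CNNSpec = CNNSpec(), *, standalone: bool = True,
              seed: int | None = None):
    """Build the VGG-style CNN; standalone mode adds the regression head.

    Trunk mode returns the bare :class:`~brainrate.nn.Sequential` feature
    extractor mapping [N, 32, 32, 5] to [N, feature_length].
    """
    model = CNNRegressor(spec, seed=seed)
    return model if standalone else model.trunk


def build_full_model(spec: FullModelSpec = FullModelSpec(), *, seed: int | None = None) -> CNNLSTMRegressor:
    """Build the shared-weight CNN + LSTM sequence regressor."""
    return CNNLSTMRegressor(spec, seed=seed)


def count_parameters(model) -> int:
    """Exact count of trainable scalars of a model or layer."""
    params = getattr(model, "params", None)
    if params is None:
        return 0
    return int(sum(p.size for p in params))
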