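"""The two classifier architectures.

* :class:`StructCnnSpec` — for the L x L structure matrices: two valid
  2 x 2 convolutions (64 then 128 filters by default), each followed by
  window-2 stride-2 floor max pooling, then dense 256 -> 128 -> C with
  softmax and dropout 0.5 after each hidden dense layer.
* :class:`OneHotCnnSpec` — for the L x 4 one-hot matrix: parallel valid
  convolutions of widths 2,4,...,16 (512 filters per width by default)
  spanning all four base columns, each globally max-pooled, concatenated,
  then dense 1024 -> C with softmax and dropout 0.7.

With the default hyperparameters the trainable-parameter totals are
4,485,255 for the one-hot network (135 classes) and 78,748,399 for the
structure network (47 classes, single channel); ``count_parameters``
reproduces these closed-form, independently of the built network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass(frozen=True)
class StructCnnSpec:
    """Hyperparameters of the structure-matrix CNN."""

    input_len: int = 200
    channels: int = 1  # 1 for probability/pair, 2 for mixed
    conv_kernels: tuple[tuple[int, int], ...] = ((2, 64), (2, 128))
    pool_window: int = 2
    fc_units: tuple[int, ...] = (256, 128)
    dropout: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 32
    classes: int = 2

    def shape_trace(self) -> list[int]:
        """Spatial side length after each conv/pool stage (valid conv, floor pool)."""
        sizes = [self.input_len]
        s = self.input_len
        for size, _ in self.conv_kernels:
            if s < size:
                raise ValueError(f"feature map {s} smaller than conv kernel {size}")
            s = s - size + 1
            sizes.append(s)
            s = s // self.pool_window
            if s < 1:
                raise ValueError("feature map vanishes after pooling; input_len too small")
            sizes.append(s)
        return sizes

    def validate(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 or 2")
        self.shape_trace()


@dataclass(frozen=True)
class OneHotCnnSpec:
    """Hyperparameters of the one-hot CNN."""

    input_len: int = 200
    alphabet: int = 4
    filter_widths: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16)
    kernels_per_width: int = 512
    fc_units: tuple[int, ...] = (1024,)
    dropout: float = 0.7
    learning_rate: float = 0.001
    batch_size: int = 64
    classes: int = 2

    def validate(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if not self.filter_widths:
            raise ValueError("need at least one filter width")
        if max(self.filter_widths) > self.input_len:
            raise ValueError(
                f"filter width {max(self.filter_widths)} exceeds input length {self.input_len}"
            )


def count_parameters(spec: StructCnnSpec | OneHotCnnSpec) -> int:
    """Closed-form count of trainable weights and biases.

    Convolution stage: kernel volume x filters + one bias per filter;
    dense stage: fan-in x units + units; dropout and pooling contribute
    nothing. Must equal the built network's reported count.
    """
    if isinstance(spec, StructCnnSpec):
        spec.validate()
        total = 0
        c_in = spec.channels
        trace = spec.shape_trace()
        for size, count in spec.conv_kernels:
            total += size * size * c_in * count + count
            c_in = count
        fan_in = trace[-1] * trace[-1] * spec.conv_kernels[-1][1]
        for units in spec.fc_units:
            total += fan_in * units + units
            fan_in = units
        total += fan_in * spec.classes + spec.classes
        return total
    if isinstance(spec, OneHotCnnSpec):
        spec.validate()
        total = 0
        for w in spec.filter_widths:
            total += w * spec.alphabet * spec.kernels_per_width + spec.kernels_per_width
        fan_in = len(spec.filter_widths) * spec.kernels_per_width
        for units in spec.fc_units:
            total += fan_in * units + units
            fan_in = units
        total += fan_in * spec.classes + spec.classes
        return total
    raise TypeError(f"unknown spec type {type(spec).__name__}")


class StructCnn:
    """Sequential CNN over (B, L, L, channels) structure matrices."""

    def __init__(self, spec: StructCnnSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 1]).generate_state(1)[0]
        )
        layers: list[nn.Layer] = []
        c_in = spec.channels
        for size, count in spec.conv_kernels:
            layers += [nn.Conv2D(size, size, c_in, count, rng), nn.ReLU(),
                       nn.MaxPool2D(spec.pool_window)]
            c_in = count
        layers.append(nn.Flatten())
        trace = spec.shape_trace()
        fan_in = trace[-1] * trace[-1] * c_in
        for units in spec.fc_units:
            layers += [nn.Dense(fan_in, units, rng), nn.ReLU(),
                       nn.Dropout(spec.dropout, self.dropout_rng)]
            fan_in = units
        layers.append(nn.Dense(fan_in, spec.classes, rng))
        self.net = nn.Sequential(layers)

    def params(self):
        return self.net.params()

    def num_parameters(self) -> int:
        return nn.num_parameters(self.net)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 3:  # single-channel grids arrive as (B, L, L)
            x = x[..., None]
        return self.net.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return _batched_proba(self, x, batch_size)


class OneHotCnn:
    """Parallel multi-width CNN over (B, L, 4) one-hot matrices."""

    def __init__(self, spec: OneHotCnnSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 1]).generate_state(1)[0]
        )
        self.branches = []
        for w in spec.filter_widths:
            self.branches.append(
                (nn.Conv1D(w, spec.alphabet, spec.kernels_per_width, rng),
                 nn.ReLU(), nn.GlobalMaxPool1D())
            )
        head: list[nn.Layer] = [nn.Dropout(spec.dropout, self.dropout_rng)]
        fan_in = len(spec.filter_widths) * spec.kernels_per_width
        for units in spec.fc_units:
            head += [nn.Dense(fan_in, units, rng), nn.ReLU(),
                     nn.Dropout(spec.dropout, self.dropout_rng)]
            fan_in = units
        head.append(nn.Dense(fan_in, spec.classes, rng))
        self.head = nn.Sequential(head)

    def params(self):
        out = []
        for conv, _, _ in self.branches:
            out.extend(conv.params())
        out.extend(self.head.params())
        return out

    def num_parameters(self) -> int:
        return nn.num_parameters(self)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pooled = []
        for conv, relu, gmp in self.branches:
            pooled.append(gmp.forward(relu.forward(conv.forward(x, train), train), train))
        self._widths = [p.shape[1] for p in pooled]
        feats = np.concatenate(pooled, axis=1)
        return self.head.forward(feats, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeats = self.head.backward(dlogits)
        offset = 0
        dx = None
        for (conv, relu, gmp), nf in zip(self.branches, self._widths):
            dpool = dfeats[:, offset : offset + nf]
            offset += nf
            dxb = conv.backward(relu.backward(gmp.backward(dpool)))
            dx = dxb if dx is None else dx + dxb

    def conv_activations(self, x: np.ndarray) -> dict[int, np.ndarray]:
        """Post-ReLU convolution response maps keyed by filter width.

        Each value has shape (B, L - w + 1, filters): the pre-pooling
        activations used for motif extraction.
        """
        out = {}
        for (conv, relu, _), w in zip(self.branches, self.spec.filter_widths):
            out[w] = relu.forward(conv.forward(x, train=False), train=False)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return _batched_proba(self, x, batch_size)


def _batched_proba(model, x: np.ndarray, batch_size: int) -> np.ndarray:
    chunks = []
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start : start + batch_size], train=False)
        chunks.append(nn.softmax(logits))
    return np.concatenate(chunks, axis=0)


def build_struct_cnn(spec: StructCnnSpec, seed: int = 0) -> StructCnn:
    """Instantiate the structure-matrix CNN (raises if L is too small)."""
    return StructCnn(spec, seed=seed)


def build_onehot_cnn(spec: OneHotCnnSpec, seed: int = 0) -> OneHotCnn:
    """Instantiate the one-hot CNN (raises if any width exceeds L)."""
    return OneHotCnn(spec, seed=seed)
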