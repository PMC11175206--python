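"""Client-side model machinery for the federated simulator.

Defines the two network families used by the simulator (a plain-SGD DNN and a
small CNN), a flat-parameter-vector representation so the server can aggregate
models arithmetically, one-round local training, and evaluation.

Conventions fixed here and relied on everywhere else:

* parameters flatten in layer order, weights before biases, row-major;
* the optimizer is plain mini-batch SGD, ``w <- w - lr * grad``;
* the loss is mean categorical cross-entropy over samples (one-hot targets);
* accuracy ties break toward the lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import nn

__all__ = [
    "ModelSpec",
    "ModelParameters",
    "ClientDataset",
    "ClientConfig",
    "ConfigurationError",
    "build_model",
    "sgd_step",
    "local_update",
    "evaluate_model",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Raised for invalid model or training configuration."""


# ---------------------------------------------------------------------------
# specs and parameter container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    ``dnn``: flattened input -> four hidden ReLU layers of ``hidden_width``
    -> softmax output.  ``cnn``: three valid-padding 3x3 convolutions with
    ``conv_filters`` channels and ReLU (no pooling), flatten, two hidden ReLU
    layers of ``hidden_width``, softmax output.
    """

    kind: str
    input_shape: tuple[int, ...]
    num_classes: int
    hidden_width: int = 500
    conv_filters: int = 32
    conv_kernel: int = 3

    N_HIDDEN_DNN = 4
    N_CONV = 3
    N_HIDDEN_CNN = 2

    def __post_init__(self):
        if self.kind not in ("dnn", "cnn"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        if any(s <= 0 for s in self.input_shape):
            raise ConfigurationError(f"non-positive input_shape {self.input_shape}")
        if self.num_classes <= 0:
            raise ConfigurationError(f"num_classes must be positive, got {self.num_classes}")
        if self.hidden_width <= 0 or self.conv_filters <= 0 or self.conv_kernel <= 0:
            raise ConfigurationError("widths, filters and kernel must be positive")
        if self.kind == "cnn":
            self._conv_output_side()  # validates feasibility

    def _image_dims(self) -> tuple[int, int, int]:
        if len(self.input_shape) == 2:
            h, w = self.input_shape
            c = 1
        elif len(self.input_shape) == 3:
            h, w, c = self.input_shape
        else:
            raise ConfigurationError(
                f"cnn input_shape must be (H, W) or (H, W, C), got {self.input_shape}"
            )
        return h, w, c

    def _conv_output_side(self) -> tuple[int, int]:
        h, w, _ = self._image_dims()
        shrink = self.N_CONV * (self.conv_kernel - 1)
        ho, wo = h - shrink, w - shrink
        if ho < 1 or wo < 1:
            raise ConfigurationError(
                f"input {h}x{w} too small for {self.N_CONV} convolutions "
                f"with kernel {self.conv_kernel}"
            )
        return ho, wo

    @property
    def input_dim(self) -> int:
        return int(np.prod(self.input_shape))

    def layout(self) -> list[tuple[str, tuple[int, ...]]]:
        """Ordered (name, shape) entries defining the flat-vector layout."""
        entries: list[tuple[str, tuple[int, ...]]] = []
        if self.kind == "dnn":
            widths = [self.input_dim] + [self.hidden_width] * self.N_HIDDEN_DNN + [self.num_classes]
            for i in range(len(widths) - 1):
                entries.append((f"dense{i}.W", (widths[i], widths[i + 1])))
                entries.append((f"dense{i}.b", (widths[i + 1],)))
        else:
            _, _, c = self._image_dims()
            cin = c
            k, f = self.conv_kernel, self.conv_filters
            for i in range(self.N_CONV):
                entries.append((f"conv{i}.W", (k, k, cin, f)))
                entries.append((f"conv{i}.b", (f,)))
                cin = f
            ho, wo = self._conv_output_side()
            widths = [ho * wo * f] + [self.hidden_width] * self.N_HIDDEN_CNN + [self.num_classes]
            for i in range(len(widths) - 1):
                entries.append((f"dense{i}.W", (widths[i], widths[i + 1])))
                entries.append((f"dense{i}.b", (widths[i + 1],)))
        return entries

    def num_parameters(self) -> int:
        return sum(int(np.prod(shape)) for _, shape in self.layout())


@dataclass
class ModelParameters:
    """All trainable weights of one network as a flat float64 vector."""

    values: np.ndarray
    layout: list[tuple[str, tuple[int, ...]]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.layout = [(name, tuple(shape)) for name, shape in self.layout]
        expected = sum(int(np.prod(shape)) for _, shape in self.layout)
        if self.values.size != expected:
            raise ValueError(
                f"flat vector has {self.values.size} entries, layout requires {expected}"
            )

    def unflatten(self) -> dict[str, np.ndarray]:
        out = {}
        offset = 0
        for name, shape in self.layout:
            size = int(np.prod(shape))
            out[name] = self.values[offset : offset + size].reshape(shape)
            offset += size
        return out

    @classmethod
    def flatten(cls, arrays: dict[str, np.ndarray],
                layout: Sequence[tuple[str, tuple[int, ...]]]) -> "ModelParameters":
        parts = [np.asarray(arrays[name], dtype=np.float64).ravel() for name, _ in layout]
        return cls(np.concatenate(parts) if parts else np.empty(0), list(layout))

    def copy(self) -> "ModelParameters":
        return ModelParameters(self.values.copy(), list(self.layout))

    def same_layout(self, other: "ModelParameters") -> bool:
        return self.layout == other.layout


@dataclass
class ClientDataset:
    """One client's private labeled data."""

    features: np.ndarray
    labels: np.ndarray
    client_id: str | int = 0

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if self.features.shape[0] < 1:
            raise ValueError("dataset must contain at least one sample")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative integers")

    @property
    def n_samples(self) -> int:
        return int(self.features.shape[0])

    @property
    def label_class_count(self) -> int:
        """Number of distinct labels actually present in this client's data."""
        return int(np.unique(self.labels).size)


@dataclass(frozen=True)
class ClientConfig:
    learning_rate: float = 0.01
    batch_size: int = 32
    local_epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.local_epochs < 1:
            raise ConfigurationError("batch_size and local_epochs must be >= 1")


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _as_network_input(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    if spec.kind == "dnn":
        flat = x.reshape(x.shape[0], -1)
        if flat.shape[1] != spec.input_dim:
            raise ValueError(
                f"feature dimension {flat.shape[1]} does not match spec input {spec.input_dim}"
            )
        return flat
    h, w, c = spec._image_dims()
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[1:] != (h, w, c):
        raise ValueError(f"image shape {x.shape[1:]} does not match spec {(h, w, c)}")
    return x


def _forward(spec: ModelSpec, params: dict[str, np.ndarray], x: np.ndarray):
    """Logits plus the per-layer caches needed for backprop."""
    caches = []
    a = x
    if spec.kind == "cnn":
        for i in range(spec.N_CONV):
            a, c1 = nn.conv2d_forward(a, params[f"conv{i}.W"], params[f"conv{i}.b"])
            a, c2 = nn.relu_forward(a)
            caches.append(("conv", i, c1, c2))
        flat_shape = a.shape
        a = a.reshape(a.shape[0], -1)
        caches.append(("flatten", flat_shape, None, None))
        n_dense = spec.N_HIDDEN_CNN + 1
    else:
        n_dense = spec.N_HIDDEN_DNN + 1
    for i in range(n_dense):
        a, c1 = nn.dense_forward(a, params[f"dense{i}.W"], params[f"dense{i}.b"])
        if i < n_dense - 1:
            a, c2 = nn.relu_forward(a)
        else:
            c2 = None
        caches.append(("dense", i, c1, c2))
    return a, caches


def _backward(spec: ModelSpec, caches, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    da = dlogits
    for entry in reversed(caches):
        kind = entry[0]
        if kind == "dense":
            _, i, c1, c2 = entry
            if c2 is not None:
                da = nn.relu_backward(da, c2)
            da, dw, db = nn.dense_backward(da, c1)
            grads[f"dense{i}.W"] = dw
            grads[f"dense{i}.b"] = db
        elif kind == "flatten":
            da = da.reshape(entry[1])
        else:  # conv
            _, i, c1, c2 = entry
            da = nn.relu_backward(da, c2)
            da, dw, db = nn.conv2d_backward(da, c1)
            grads[f"conv{i}.W"] = dw
            grads[f"conv{i}.b"] = db
    return grads


def loss_and_gradients(spec: ModelSpec, model: ModelParameters,
                       x: np.ndarray, y: np.ndarray) -> tuple[float, ModelParameters]:
    """Mean cross-entropy on (x, y) and its gradient in flat-vector form."""
    params = model.unflatten()
    xin = _as_network_input(spec, x)
    onehot = _one_hot(y, spec.num_classes)
    logits, caches = _forward(spec, params, xin)
    loss, dlogits = nn.softmax_cross_entropy(logits, onehot)
    grads = _backward(spec, caches, dlogits)
    return loss, ModelParameters.flatten(grads, model.layout)


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.intp)
    if labels.size and labels.max() >= num_classes:
        raise ValueError(f"label {labels.max()} out of range for {num_classes} classes")
    out = np.zeros((labels.size, num_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_model(spec: ModelSpec, seed: int) -> ModelParameters:
    """Deterministically initialize a network: Glorot-uniform weights, zero biases."""
    rng = np.random.default_rng(seed)
    arrays = {}
    for name, shape in spec.layout():
        if name.endswith(".b"):
            arrays[name] = np.zeros(shape)
        else:
            arrays[name] = nn.glorot_uniform(rng, shape)
    return ModelParameters.flatten(arrays, spec.layout())


def sgd_step(values: np.ndarray, gradient: np.ndarray, learning_rate: float) -> np.ndarray:
    """One plain gradient-descent step ``w <- w - lr * grad`` on flat vectors."""
    values = np.asarray(values, dtype=np.float64)
    gradient = np.asarray(gradient, dtype=np.float64)
    if values.shape != gradient.shape:
        raise ValueError("parameter and gradient shapes differ")
    return values - learning_rate * gradient


def local_update(model: ModelParameters, data: ClientDataset, cfg: ClientConfig,
                 spec: ModelSpec) -> ModelParameters:
    """One client's local training pass: ``cfg.local_epochs`` epochs of seeded
    mini-batch SGD on mean cross-entropy.  The input model is not modified."""
    rng = np.random.default_rng(cfg.seed)
    current = model.copy()
    n = data.n_samples
    for _ in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, grad = loss_and_gradients(spec, current, data.features[idx], data.labels[idx])
            current = ModelParameters(
                sgd_step(current.values, grad.values, cfg.learning_rate), current.layout
            )
    return current


def evaluate_model(model: ModelParameters, data: ClientDataset, spec: ModelSpec,
                   batch_size: int = 256) -> tuple[float, float]:
    """Mean cross-entropy loss and argmax accuracy on a dataset."""
    if data.n_samples < 1:
        raise ValueError("cannot evaluate on an empty dataset")
    params = model.unflatten()
    total_nll = 0.0
    correct = 0
    onehot_all = _one_hot(data.labels, spec.num_classes)
    for start in range(0, data.n_samples, batch_size):
        x = _as_network_input(spec, data.features[start : start + batch_size])
        logits, _ = _forward(spec, params, x)
        probs = nn.softmax(logits)
        onehot = onehot_all[start : start + batch_size]
        total_nll += -np.sum(onehot * np.log(np.clip(probs, 1e-300, None)))
        correct += int(np.sum(np.argmax(logits, axis=1) == data.labels[start : start + batch_size]))
    return total_nll / data.n_samples, correct / data.n_samples


# ---------------------------------------------------------------------------
# checkpoints: named-array archive + JSON layout sidecar
# ---------------------------------------------------------------------------


def save_checkpoint(model: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    np.savez(path, **model.unflatten())
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps({"layout": [[n, list(s)] for n, s in model.layout]}))


def load_checkpoint(path: str | Path) -> ModelParameters:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(".json")
    layout = [(n, tuple(s)) for n, s in json.loads(sidecar.read_text())["layout"]]
    with np.load(path) as archive:
        arrays = {name: archive[name] for name, _ in layout}
    return ModelParameters.flatten(arrays, layout)
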