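"""Convolutional-recurrent sample-wise ECG wave classifiers.

The model family: a stack of 1-D convolutions (kernel 3, stride 1,
same-padding, ReLU) whose filter counts are a prefix of
(8, 16, 32, 64, 128, 256, 512, 1024, 2048), followed by a recurrent head
(LSTM, BiLSTM, GRU, or BiGRU) that emits an output at every timestep, and
a per-timestep dense layer of width 4 with softmax.  Thirteen standard
configurations exist: ids 1-4 pair 1-4 conv layers with an LSTM head,
ids 5-13 pair 1-9 conv layers with a BiLSTM head.  Because the conv stack
uses same-padding and no pooling, the temporal length is preserved end to
end, so each of the 512 input samples receives a 4-class probability row
(isoelectric / P / QRS / T).

Layers are implemented directly on numpy arrays of shape
(batch, time, channels), with hand-derived backward passes (backprop
through time for the recurrent heads) and an Adam optimizer.  Gradients
are exercised against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FILTER_LADDER",
    "ModelConfig",
    "TrainConfig",
    "enumerate_configs",
    "build_network",
    "count_params",
    "predict_labels",
    "SequenceLabeler",
    "Adam",
    "softmax",
]

#: Filter counts available to the conv stack; a config uses a prefix.
FILTER_LADDER = (8, 16, 32, 64, 128, 256, 512, 1024, 2048)

HEADS = ("LSTM", "BiLSTM", "GRU", "BiGRU")


@dataclass(frozen=True)
class ModelConfig:
    """One convolutional-recurrent configuration."""

    model_id: int | str
    conv_filters: tuple[int, ...]
    head: str
    kernel_size: int = 3
    stride: int = 1
    head_units: int = 64  # per direction
    n_classes: int = 4
    input_length: int = 512

    def __post_init__(self) -> None:
        depth = len(self.conv_filters)
        if not (1 <= depth <= len(FILTER_LADDER)):
            raise ValueError(f"conv depth must be 1..{len(FILTER_LADDER)}, got {depth}")
        if self.conv_filters != FILTER_LADDER[:depth]:
            raise ValueError(
                f"conv_filters must be the prefix {FILTER_LADDER[:depth]} of the "
                f"filter ladder, got {self.conv_filters}"
            )
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}, got {self.head!r}")
        if self.kernel_size != 3 or self.stride != 1:
            raise ValueError("the model family fixes kernel_size=3, stride=1")
        if self.head_units < 1 or self.n_classes < 2 or self.input_length < 1:
            raise ValueError("head_units, n_classes, input_length must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults are the full-scale schedule
    (300 epochs, batch 8, learning rate 1e-5, categorical cross-entropy)."""

    epochs: int = 300
    batch_size: int = 8
    learning_rate: float = 1e-5
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def enumerate_configs(
    head_units: int = 64, input_length: int = 512
) -> list[ModelConfig]:
    """The 13 standard configurations: 1-4 conv + LSTM, then 1-9 conv + BiLSTM."""
    configs = []
    for model_id in range(1, 5):
        configs.append(ModelConfig(
            model_id=model_id, conv_filters=FILTER_LADDER[:model_id],
            head="LSTM", head_units=head_units, input_length=input_length,
        ))
    for model_id in range(5, 14):
        configs.append(ModelConfig(
            model_id=model_id, conv_filters=FILTER_LADDER[: model_id - 4],
            head="BiLSTM", head_units=head_units, input_length=input_length,
        ))
    return configs


# ---------------------------------------------------------------------------
# Layers.  Every layer exposes forward(x) -> y and backward(dy) -> dx, with
# parameter gradients accumulated into .grads between zero_grads() calls.
# Arrays are (batch, time, channels) throughout.
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), max(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:n, :m]


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv1D(Layer):
    """Same-padding 1-D convolution, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator):
        self.k = kernel_size
        self.params = {
            "W": _glorot(rng, (kernel_size, in_ch, out_ch),
                         kernel_size * in_ch, kernel_size * out_ch),
            "b": np.zeros(out_ch),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        self._xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._t = x.shape[1]
        W, b = self.params["W"], self.params["b"]
        y = np.zeros((x.shape[0], self._t, W.shape[2]))
        for j in range(self.k):
            y += self._xp[:, j : j + self._t, :] @ W[j]
        return y + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        pad = self.k // 2
        dxp = np.zeros_like(self._xp)
        self.grads["b"] += dy.sum(axis=(0, 1))
        for j in range(self.k):
            self.grads["W"][j] += np.tensordot(
                self._xp[:, j : j + self._t, :], dy, axes=([0, 1], [0, 1])
            )
            dxp[:, j : j + self._t, :] += dy @ W[j].T
        return dxp[:, pad : pad + self._t, :]


class ReLU(Layer):
    params: dict[str, np.ndarray] = {}

    def __init__(self) -> None:
        self.params = {}
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Unidirectional LSTM returning the full hidden sequence."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        W = _glorot(rng, (in_dim, 4 * units), in_dim, units)
        U = np.concatenate(
            [_orthogonal(rng, units, units) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = {"W": W, "U": U, "b": b}
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        xW = x @ W + b
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._gates = np.zeros((B, T, 4 * H))
        self._c = np.zeros((B, T, H))
        self._hprev = np.zeros((B, T, H))
        out = np.zeros((B, T, H))
        for t in range(T):
            z = xW[:, t] + h @ U
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            self._hprev[:, t] = h
            c_prev = c
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            self._gates[:, t, :H] = i
            self._gates[:, t, H : 2 * H] = f
            self._gates[:, t, 2 * H : 3 * H] = g
            self._gates[:, t, 3 * H :] = o
            self._c[:, t] = c
            out[:, t] = h
        self._out = out
        return out

    def backward(self, dH: np.ndarray) -> np.ndarray:
        B, T, H = dH.shape
        U = self.params["U"]
        dZ = np.zeros((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = self._gates[:, t, :H]
            f = self._gates[:, t, H : 2 * H]
            g = self._gates[:, t, 2 * H : 3 * H]
            o = self._gates[:, t, 3 * H :]
            c = self._c[:, t]
            c_prev = self._c[:, t - 1] if t > 0 else np.zeros((B, H))
            tanh_c = np.tanh(c)
            dh = dH[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dZ[:, t] = dz
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads["W"] += np.tensordot(self._x, dZ, axes=([0, 1], [0, 1]))
        self.grads["U"] += np.tensordot(self._hprev, dZ, axes=([0, 1], [0, 1]))
        self.grads["b"] += dZ.sum(axis=(0, 1))
        return dZ @ self.params["W"].T


class GRU(Layer):
    """Unidirectional GRU returning the full hidden sequence.

    Gate order in the packed weight matrices: update z, reset r, candidate n;
    the candidate uses the reset-gated previous state, n = tanh(xWn + (r*h)Un + bn).
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        W = _glorot(rng, (in_dim, 3 * units), in_dim, units)
        U = np.concatenate(
            [_orthogonal(rng, units, units) for _ in range(3)], axis=1
        )
        self.params = {"W": W, "U": U, "b": np.zeros(3 * units)}
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        Uz, Ur, Un = U[:, :H], U[:, H : 2 * H], U[:, 2 * H :]
        xW = x @ W + b
        h = np.zeros((B, H))
        self._x = x
        self._z = np.zeros((B, T, H))
        self._r = np.zeros((B, T, H))
        self._n = np.zeros((B, T, H))
        self._hprev = np.zeros((B, T, H))
        self._rh = np.zeros((B, T, H))
        out = np.zeros((B, T, H))
        for t in range(T):
            z = _sigmoid(xW[:, t, :H] + h @ Uz)
            r = _sigmoid(xW[:, t, H : 2 * H] + h @ Ur)
            rh = r * h
            n = np.tanh(xW[:, t, 2 * H :] + rh @ Un)
            self._hprev[:, t] = h
            self._z[:, t], self._r[:, t], self._n[:, t], self._rh[:, t] = z, r, n, rh
            h = (1 - z) * n + z * h
            out[:, t] = h
        return out

    def backward(self, dH: np.ndarray) -> np.ndarray:
        B, T, H = dH.shape
        U = self.params["U"]
        Uz, Ur, Un = U[:, :H], U[:, H : 2 * H], U[:, 2 * H :]
        dA = np.zeros((B, T, 3 * H))
        dh_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            z, r, n = self._z[:, t], self._r[:, t], self._n[:, t]
            h_prev = self._hprev[:, t]
            dh = dH[:, t] + dh_next
            dz = dh * (h_prev - n)
            dn = dh * (1 - z)
            dh_prev = dh * z
            da_n = dn * (1 - n**2)
            drh = da_n @ Un.T
            dr = drh * h_prev
            dh_prev += drh * r
            da_z = dz * z * (1 - z)
            da_r = dr * r * (1 - r)
            dh_prev += da_z @ Uz.T + da_r @ Ur.T
            dA[:, t, :H] = da_z
            dA[:, t, H : 2 * H] = da_r
            dA[:, t, 2 * H :] = da_n
            dh_next = dh_prev
        self.grads["W"] += np.tensordot(self._x, dA, axes=([0, 1], [0, 1]))
        dU = np.zeros_like(U)
        dU[:, : 2 * H] = np.tensordot(self._hprev, dA[:, :, : 2 * H], axes=([0, 1], [0, 1]))
        dU[:, 2 * H :] = np.tensordot(self._rh, dA[:, :, 2 * H :], axes=([0, 1], [0, 1]))
        self.grads["U"] += dU
        self.grads["b"] += dA.sum(axis=(0, 1))
        return dA @ self.params["W"].T


class Bidirectional(Layer):
    """Run one recurrent layer forward in time and a twin backward; concat."""

    def __init__(self, fwd: Layer, bwd: Layer):
        self.fwd, self.bwd = fwd, bwd
        self.params = {}
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = dy.shape[2] // 2
        dxf = self.fwd.backward(dy[:, :, :H])
        dxb = self.bwd.backward(dy[:, ::-1, H:])[:, ::-1, :]
        return dxf + dxb

    def zero_grads(self) -> None:
        self.grads = {}
        if hasattr(self, "fwd"):
            self.fwd.zero_grads()
            self.bwd.zero_grads()


class Dense(Layer):
    """Time-distributed affine layer."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.params = {
            "W": _glorot(rng, (in_dim, out_dim), in_dim, out_dim),
            "b": np.zeros(out_dim),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += np.tensordot(self._x, dy, axes=([0, 1], [0, 1]))
        self.grads["b"] += dy.sum(axis=(0, 1))
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SequenceLabeler:
    """A conv stack + recurrent head + per-timestep softmax classifier."""

    def __init__(self, config: ModelConfig, layers: Sequence[Layer]):
        self.config = config
        self.layers = list(layers)

    def parameters(self):
        """Yield (layer, name, array) for every trainable tensor."""
        for layer in self._flat_layers():
            for name, value in layer.params.items():
                yield layer, name, value

    def _flat_layers(self):
        for layer in self.layers:
            if isinstance(layer, Bidirectional):
                yield layer.fwd
                yield layer.bwd
            else:
                yield layer

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, time) or (batch, time, 1) -> logits (batch, time, n_classes)."""
        if x.ndim == 2:
            x = x[:, :, None]
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(x))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def loss_and_grad(
        self, x: np.ndarray, y: np.ndarray, mask: np.ndarray
    ) -> float:
        """Masked categorical cross-entropy; accumulates parameter gradients.

        y: (batch, time) integer classes; mask: (batch, time) boolean, True on
        real (non-padded) samples.  Returns mean loss over masked samples.
        """
        logits = self.forward_logits(x)
        p = softmax(logits)
        B, T, C = logits.shape
        n_valid = int(mask.sum())
        if n_valid == 0:
            raise ValueError("mask excludes every sample")
        idx_b, idx_t = np.nonzero(mask)
        picked = p[idx_b, idx_t, y[idx_b, idx_t]]
        loss = -float(np.mean(np.log(np.clip(picked, 1e-12, None))))
        onehot = np.zeros_like(p)
        onehot[idx_b, idx_t, y[idx_b, idx_t]] = 1.0
        dlogits = (p - onehot) * mask[:, :, None] / n_valid
        self.backward(dlogits)
        return loss


class Adam:
    """Adam optimizer over a model's parameter tensors."""

    def __init__(self, model: SequenceLabeler, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, _, p in model.parameters()]
        self.v = [np.zeros_like(p) for _, _, p in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, (layer, name, p) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def build_network(config: ModelConfig, seed: int = 0) -> SequenceLabeler:
    """Build an initialized model for one configuration."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    in_ch = 1
    for out_ch in config.conv_filters:
        layers.append(Conv1D(in_ch, out_ch, config.kernel_size, rng))
        layers.append(ReLU())
        in_ch = out_ch
    units = config.head_units
    if config.head == "LSTM":
        layers.append(LSTM(in_ch, units, rng))
        head_out = units
    elif config.head == "GRU":
        layers.append(GRU(in_ch, units, rng))
        head_out = units
    elif config.head == "BiLSTM":
        layers.append(Bidirectional(LSTM(in_ch, units, rng), LSTM(in_ch, units, rng)))
        head_out = 2 * units
    else:  # BiGRU
        layers.append(Bidirectional(GRU(in_ch, units, rng), GRU(in_ch, units, rng)))
        head_out = 2 * units
    layers.append(Dense(head_out, config.n_classes, rng))
    return SequenceLabeler(config, layers)


def count_params(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    total = 0
    in_ch = 1
    for out_ch in config.conv_filters:
        total += config.kernel_size * in_ch * out_ch + out_ch
        in_ch = out_ch
    H = config.head_units
    gates = 4 if "LSTM" in config.head else 3
    per_direction = gates * (in_ch * H + H * H + H)
    directions = 2 if config.head.startswith("Bi") else 1
    total += directions * per_direction
    total += directions * H * config.n_classes + config.n_classes
    return total


def save_checkpoint(model: SequenceLabeler, path) -> None:
    """Save weights as .npz with the config as a JSON sidecar (self-describing)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    arrays = {
        f"{i}.{name}": value
        for i, (_, name, value) in enumerate(model.parameters())
    }
    np.savez(path, **arrays)
    cfg = asdict(model.config)
    Path(str(path) + ".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> SequenceLabeler:
    import json
    from pathlib import Path

    cfg = json.loads(Path(str(path) + ".json").read_text())
    cfg["conv_filters"] = tuple(cfg["conv_filters"])
    model = build_network(ModelConfig(**cfg), seed=0)
    npz = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    data = np.load(npz)
    for i, (layer, name, value) in enumerate(model.parameters()):
        layer.params[name][...] = data[f"{i}.{name}"]
    return model


def predict_labels(model: SequenceLabeler, beat) -> np.ndarray:
    """Per-sample argmax labels for one beat window (ties -> lower class)."""
    signal = np.asarray(beat.signal if hasattr(beat, "signal") else beat, dtype=np.float64)
    if signal.shape != (model.config.input_length,):
        raise ValueError(
            f"expected a beat of length {model.config.input_length}, "
            f"got shape {signal.shape}"
        )
    proba = model.predict_proba(signal[None, :])
    return np.argmax(proba[0], axis=-1)
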