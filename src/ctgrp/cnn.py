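"""Compact convolutional classifier for recurrence-plot images.

The default network is the 8-layer architecture (counting input, two
convolution blocks, two average-pooling layers, two fully-connected
layers and the softmax output; batch-norm/ReLU/dropout ride along with
their host layers): 64x64x3 input -> conv 5x5x8 (stride 1, no padding)
-> batch norm -> ReLU -> average pool 3x3 (stride 2) -> conv 5x5x8 ->
batch norm -> ReLU -> average pool 3x3 (stride 2) -> dense 144 ->
dropout 0.8 -> dense 2 -> softmax, trained with cross-entropy loss, L2
weight decay, and a choice of SGD-with-momentum / Adam / RMSProp. The
Adam "gradient decay factor" (0.6) follows the naming of the original
training toolbox and is the first-moment decay; the squared-gradient
decay keeps its conventional 0.999.

Everything is implemented directly on NumPy arrays (convolutions as
accumulated kernel-offset matmuls with explicit backward passes); the
arrays are small enough that a CPU handles the full training loop
comfortably. Images are zero-centered
with the training-set mean pixel value before entering the network;
evaluation mode disables dropout and uses the batch-norm running
statistics, so prediction is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LayerSpec",
    "TrainConfig",
    "conv_output_size",
    "default_architecture",
    "architecture_from_code",
    "TABLE_ARCHITECTURES",
    "CNNModel",
    "build",
    "train",
    "predict",
]


def conv_output_size(in_size: int, kernel: int, stride: int = 1, padding: int = 0) -> int:
    """Spatial output size of a convolution/pooling window sweep.

    ``floor((in_size - kernel + 2*padding) / stride) + 1``; raises if the
    window does not fit.
    """
    out = (in_size - kernel + 2 * padding) // stride + 1
    if out < 1:
        raise ValueError(f"kernel {kernel} (stride {stride}, padding {padding}) "
                         f"does not fit input of size {in_size}")
    return out


@dataclass
class LayerSpec:
    kind: str                       # input|convolution|batch-norm|relu|average-pool|
                                    # fully-connected|dropout|softmax-output
    kernel: int = 0
    n_filters: int = 0
    stride: int = 1
    padding: int = 0
    units: int = 0
    drop_prob: float = 0.0
    size: int = 64                  # input layer spatial size
    channels: int = 3               # input layer channel count

    def __post_init__(self) -> None:
        if self.kind in ("convolution", "average-pool"):
            if self.kernel < 1 or self.stride < 1:
                raise ValueError(f"{self.kind}: kernel and stride must be >= 1")
            if self.padding < 0:
                raise ValueError(f"{self.kind}: padding must be >= 0")
        if self.kind == "dropout" and not (0.0 <= self.drop_prob < 1.0):
            raise ValueError("drop_prob must be in [0, 1)")


def _conv_block(n_filters: int = 8, kernel: int = 5) -> List[LayerSpec]:
    return [LayerSpec("convolution", kernel=kernel, n_filters=n_filters),
            LayerSpec("batch-norm"), LayerSpec("relu")]


TABLE_ARCHITECTURES: Dict[int, str] = {
    5: "I-C-P-F-O",
    6: "I-C-P-C-F-O",
    7: "I-C-P-C-P-F-O",
    8: "I-C-P-C-P-F-F-O",
    9: "I-C-P-C-P-C-F-F-O",
    10: "I-C-P-C-P-C-P-F-F-O",
    11: "I-C-P-C-P-C-P-F-F-F-O",
    12: "I-C-P-C-P-C-P-C-F-F-F-O",
}


def architecture_from_code(code, input_size: int = 64, channels: int = 3,
                           n_filters: int = 8, hidden_units: int = 144,
                           drop_prob: float = 0.8, n_classes: int = 2) -> List[LayerSpec]:
    """Layer chain from a compact code like ``"I-C-P-C-P-F-F-O"``.

    C = 5x5 convolution (+ batch norm + ReLU), P = 3x3 average pool with
    stride 2, F = fully-connected (hidden layers get ``hidden_units``
    units followed by dropout; the final one feeds the softmax with
    ``n_classes`` units). An integer layer count selects the
    corresponding member of the 5-12-layer family.
    """
    if isinstance(code, int):
        try:
            code = TABLE_ARCHITECTURES[code]
        except KeyError:
            raise ValueError(f"no {code}-layer architecture in the 5-12 family")
    tokens = [t for t in code.split("-") if t]
    if tokens[0] != "I" or tokens[-1] != "O":
        raise ValueError(f"architecture code must start with I and end with O: {code}")
    n_fc = tokens.count("F")
    arch: List[LayerSpec] = [LayerSpec("input", size=input_size, channels=channels)]
    fc_seen = 0
    for t in tokens[1:-1]:
        if t == "C":
            arch.extend(_conv_block(n_filters=n_filters))
        elif t == "P":
            arch.append(LayerSpec("average-pool", kernel=3, stride=2))
        elif t == "F":
            fc_seen += 1
            if fc_seen < n_fc:
                arch.append(LayerSpec("fully-connected", units=hidden_units))
                arch.append(LayerSpec("dropout", drop_prob=drop_prob))
            else:
                arch.append(LayerSpec("fully-connected", units=n_classes))
        else:
            raise ValueError(f"unknown layer token {t!r} in {code}")
    arch.append(LayerSpec("softmax-output"))
    return arch


def default_architecture() -> List[LayerSpec]:
    """The 8-layer network of the diagnosis system (see module docstring)."""
    return architecture_from_code(8)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    l2_factor: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 10
    optimizer: str = "adam"         # adam | sgd | rmsp
    adam_beta1: float = 0.6         # gradient decay factor (first moment)
    adam_decay: float = 0.999       # squared-gradient decay (beta2)
    adam_epsilon: float = 1e-6
    rmsp_decay: float = 0.6         # RMSProp squared-gradient decay
    sgd_momentum: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd", "rmsp"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# Layer implementations (forward + backward on NHWC float64 arrays)
# ---------------------------------------------------------------------------

class _Layer:
    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, training: bool, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def weight_keys(self) -> Tuple[str, ...]:
        """Parameter keys subject to L2 decay (weights, not biases/norms)."""
        return ()


class _Conv(_Layer):
    def __init__(self, kernel, c_in, c_out, stride, padding, rng):
        super().__init__()
        fan_in = kernel * kernel * c_in
        limit = np.sqrt(6.0 / fan_in)
        self.params = {
            "W": rng.uniform(-limit, limit, size=(kernel, kernel, c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.kernel, self.stride, self.padding = kernel, stride, padding

    @property
    def weight_keys(self):
        return ("W",)

    def forward(self, x, training, rng=None):
        if self.padding:
            x = np.pad(x, ((0, 0), (self.padding,) * 2, (self.padding,) * 2, (0, 0)))
        k, s = self.kernel, self.stride
        W = self.params["W"]
        self._x = x
        Ho = (x.shape[1] - k) // s + 1
        Wo = (x.shape[2] - k) // s + 1
        # accumulate k*k small matmuls instead of materializing an im2col
        # tensor (memory-bound on these image sizes)
        out = np.empty((x.shape[0], Ho, Wo, W.shape[3]))
        out[:] = self.params["b"]
        for p in range(k):
            for q in range(k):
                out += x[:, p:p + Ho * s:s, q:q + Wo * s:s, :] @ W[p, q]
        return out

    def backward(self, dout):
        k, s = self.kernel, self.stride
        W = self.params["W"]
        x = self._x
        Ho, Wo = dout.shape[1], dout.shape[2]
        dW = np.empty_like(W)
        dx = np.zeros(x.shape)
        for p in range(k):
            for q in range(k):
                patch = x[:, p:p + Ho * s:s, q:q + Wo * s:s, :]
                # dW[p,q,c,f] = sum_{b,i,j} patch[b,i,j,c] * dout[b,i,j,f]
                dW[p, q] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, p:p + Ho * s:s, q:q + Wo * s:s, :] += dout @ W[p, q].T
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        if self.padding:
            pad = self.padding
            dx = dx[:, pad:-pad, pad:-pad, :]
        return dx


class _BatchNorm(_Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._n = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        g = self.params["gamma"]
        axes, n = self._axes, self._n
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=axes)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std
        return dx


class _ReLU(_Layer):
    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class _AvgPool(_Layer):
    def __init__(self, kernel, stride):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x, training, rng=None):
        k, s = self.kernel, self.stride
        self._xshape = x.shape
        Ho = (x.shape[1] - k) // s + 1
        Wo = (x.shape[2] - k) // s + 1
        out = np.zeros((x.shape[0], Ho, Wo, x.shape[3]))
        for p in range(k):
            for q in range(k):
                out += x[:, p:p + Ho * s:s, q:q + Wo * s:s, :]
        return out / (k * k)

    def backward(self, dout):
        k, s = self.kernel, self.stride
        dx = np.zeros(self._xshape)
        Ho, Wo = dout.shape[1], dout.shape[2]
        share = dout / (k * k)
        for p in range(k):
            for q in range(k):
                dx[:, p:p + Ho * s:s, q:q + Wo * s:s, :] += share
        return dx


class _Flatten(_Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        limit = np.sqrt(6.0 / n_in)
        self.params = {"W": rng.uniform(-limit, limit, size=(n_in, n_out)),
                       "b": np.zeros(n_out)}

    @property
    def weight_keys(self):
        return ("W",)

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class _Dropout(_Layer):
    def __init__(self, drop_prob):
        super().__init__()
        self.drop_prob = drop_prob

    def forward(self, x, training, rng=None):
        if not training or self.drop_prob == 0.0:
            return x
        keep = 1.0 - self.drop_prob
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CNNModel:
    """A layer chain with seeded initialization, training, and prediction.

    Build with :func:`build`; class indices follow ``classes`` order
    (default positive class first: ``("normal", "pathological")``).
    """

    def __init__(self, arch: List[LayerSpec], seed: int = 0,
                 classes: Tuple[str, str] = ("normal", "pathological")):
        self.arch = list(arch)
        self.seed = seed
        self.classes = tuple(classes)
        self.input_mean = 0.0
        self.history: List[dict] = []
        self._rng = np.random.default_rng(seed)
        self._build_layers(np.random.default_rng(seed))

    # -- construction -----------------------------------------------------
    def _build_layers(self, rng) -> None:
        if not self.arch or self.arch[0].kind != "input":
            raise ValueError("layer 1: architecture must start with an input layer")
        size, channels = self.arch[0].size, self.arch[0].channels
        self.input_shape = (size, size, channels)
        flat: Optional[int] = None
        layers: List[_Layer] = []
        shapes = [(size, size, channels)]
        for li, spec in enumerate(self.arch[1:], start=2):
            try:
                if spec.kind == "convolution":
                    if flat is not None:
                        raise ValueError("convolution after flattening")
                    size = conv_output_size(size, spec.kernel, spec.stride, spec.padding)
                    layers.append(_Conv(spec.kernel, channels, spec.n_filters,
                                        spec.stride, spec.padding, rng))
                    channels = spec.n_filters
                elif spec.kind == "batch-norm":
                    layers.append(_BatchNorm(channels if flat is None else flat))
                elif spec.kind == "relu":
                    layers.append(_ReLU())
                elif spec.kind == "average-pool":
                    if flat is not None:
                        raise ValueError("pooling after flattening")
                    size = conv_output_size(size, spec.kernel, spec.stride, spec.padding)
                    layers.append(_AvgPool(spec.kernel, spec.stride))
                elif spec.kind == "fully-connected":
                    if flat is None:
                        layers.append(_Flatten())
                        flat = size * size * channels
                    layers.append(_Dense(flat, spec.units, rng))
                    flat = spec.units
                elif spec.kind == "dropout":
                    layers.append(_Dropout(spec.drop_prob))
                elif spec.kind == "softmax-output":
                    if flat is None:
                        raise ValueError("softmax output requires a fully-connected layer")
                    self.n_classes = flat
                else:
                    raise ValueError(f"unknown layer kind {spec.kind!r}")
            except ValueError as err:
                raise ValueError(f"layer {li} ({spec.kind}): {err}") from None
            shapes.append((size, size, channels) if flat is None else (flat,))
        self.layers = layers
        self.feature_shapes = shapes
        # near-zero classifier head: early softmax outputs stay close to
        # uniform, so the first gradient steps carry feature signal rather
        # than the head's random initialization
        dense_layers = [l for l in layers if isinstance(l, _Dense)]
        if dense_layers:
            dense_layers[-1].params["W"] *= 0.01

    def feature_map_trace(self) -> List[Tuple[int, ...]]:
        """Shape after each architecture entry (input first)."""
        return list(self.feature_shapes)

    def parameter_count(self) -> int:
        return sum(p.size for l in self.layers for p in l.params.values())

    # -- inference --------------------------------------------------------
    def _prepare(self, images) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:  # (B, H, W) grayscale -> replicate channels
            x = np.repeat(x[..., None], self.input_shape[2], axis=3)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ValueError(f"expected images of shape (B,)+{self.input_shape}, "
                             f"got {x.shape}")
        return x - self.input_mean

    def _forward(self, x, training: bool, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def predict_proba(self, images) -> np.ndarray:
        """Per-image class probabilities (rows sum to 1); deterministic."""
        return _softmax(self._forward(self._prepare(images), training=False))

    def predict(self, images) -> Tuple[np.ndarray, List[str]]:
        """Probabilities and hard labels; a tie goes to the first class."""
        proba = self.predict_proba(images)
        idx = np.where(proba[:, 0] >= proba[:, 1], 0, 1)
        return proba, [self.classes[i] for i in idx]

    # -- training ---------------------------------------------------------
    def _label_indices(self, labels) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([lookup[l] for l in labels], dtype=int)
        except KeyError as bad:
            raise ValueError(f"unknown label {bad}; expected one of {self.classes}")

    def evaluate(self, images, labels) -> Tuple[float, float]:
        """(cross-entropy loss, accuracy) in evaluation mode."""
        y = self._label_indices(labels)
        proba = self.predict_proba(images)
        loss = float(-np.log(np.clip(proba[np.arange(y.size), y], 1e-12, None)).mean())
        acc = float((proba.argmax(axis=1) == y).mean())
        return loss, acc

    def fit(self, images, labels, val_images=None, val_labels=None,
            config: TrainConfig = TrainConfig()) -> "CNNModel":
        """Mini-batch training with cross-entropy loss and L2 weight decay.

        Dropout and batch statistics are active only here; the history
        records per-epoch training and validation loss/accuracy. Fully
        seeded: identical data + config + seed reproduce identical
        parameters.
        """
        y = self._label_indices(labels)
        if np.unique(y).size < 2:
            raise ValueError("training set contains a single class")
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = np.repeat(x[..., None], self.input_shape[2], axis=3)
        self.input_mean = float(x.mean())
        x = x - self.input_mean

        rng = np.random.default_rng(config.seed)
        opt = _make_optimizer(config)
        n = x.shape[0]
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            losses, accs = [], []
            for s in range(0, n, config.batch_size):
                b = order[s:s + config.batch_size]
                xb, yb = x[b], y[b]
                logits = self._forward(xb, training=True, rng=rng)
                proba = _softmax(logits)
                eps = 1e-12
                losses.append(float(-np.log(np.clip(
                    proba[np.arange(yb.size), yb], eps, None)).mean()))
                accs.append(float((proba.argmax(axis=1) == yb).mean()))
                dlogits = proba.copy()
                dlogits[np.arange(yb.size), yb] -= 1.0
                dlogits /= yb.size
                dout = dlogits
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                opt.step(self.layers, l2=config.l2_factor, lr=config.learning_rate)
            # refresh batch-norm statistics before any evaluation-mode use
            self._recompute_bn_stats(x)
            entry = dict(epoch=epoch + 1, train_loss=float(np.mean(losses)),
                         train_acc=float(np.mean(accs)))
            if val_images is not None and len(val_images) > 0:
                vloss, vacc = self.evaluate(val_images, val_labels)
                entry.update(val_loss=vloss, val_acc=vacc)
            self.history.append(entry)
        return self

    def _recompute_bn_stats(self, x: np.ndarray, max_images: int = 1024,
                            chunk: int = 256) -> None:
        """Replace batch-norm running averages with exact training-set moments.

        After only a few dozen optimizer steps the momentum-averaged
        statistics still carry their initialization, which skews
        evaluation-mode outputs; one deterministic pass over (up to
        ``max_images`` of) the already-centered training images fixes
        them. Processes layer by layer in chunks to bound memory.
        """
        x = x[:max_images]
        for target in self.layers:
            if isinstance(target, _BatchNorm):
                s = s2 = None
                count = 0
                for lo in range(0, x.shape[0], chunk):
                    z = x[lo:lo + chunk]
                    for layer in self.layers:
                        if layer is target:
                            break
                        z = layer.forward(z, training=False)
                    axes = tuple(range(z.ndim - 1))
                    zs = z.sum(axis=axes)
                    z2 = (z * z).sum(axis=axes)
                    s = zs if s is None else s + zs
                    s2 = z2 if s2 is None else s2 + z2
                    count += z.size // z.shape[-1]
                mean = s / count
                target.running_mean = mean
                target.running_var = s2 / count - mean ** 2

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: architecture + parameters + statistics."""
        blobs, meta = {}, []
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                blobs[f"l{i}_{key}"] = val
            if isinstance(layer, _BatchNorm):
                blobs[f"l{i}_running_mean"] = layer.running_mean
                blobs[f"l{i}_running_var"] = layer.running_var
        arch_json = json.dumps([asdict(s) for s in self.arch])
        np.savez(path, __arch__=arch_json, __seed__=self.seed,
                 __classes__=json.dumps(self.classes),
                 __input_mean__=self.input_mean,
                 __history__=json.dumps(self.history), **blobs)

    @classmethod
    def load(cls, path) -> "CNNModel":
        data = np.load(path, allow_pickle=False)
        arch = [LayerSpec(**d) for d in json.loads(str(data["__arch__"]))]
        model = cls(arch, seed=int(data["__seed__"]),
                    classes=tuple(json.loads(str(data["__classes__"]))))
        model.input_mean = float(data["__input_mean__"])
        model.history = json.loads(str(data["__history__"]))
        for i, layer in enumerate(model.layers):
            for key in layer.params:
                layer.params[key] = data[f"l{i}_{key}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean = data[f"l{i}_running_mean"]
                layer.running_var = data[f"l{i}_running_var"]
        return model


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class _SGDMomentum:
    def __init__(self, momentum):
        self.momentum, self.v = momentum, {}

    def step(self, layers, l2, lr):
        for i, layer in enumerate(layers):
            for key, g in layer.grads.items():
                if key in layer.weight_keys and l2:
                    g = g + l2 * layer.params[key]
                vk = self.v.setdefault((i, key), np.zeros_like(g))
                vk *= self.momentum
                vk -= lr * g
                layer.params[key] += vk


class _Adam:
    def __init__(self, beta1, beta2, eps):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, layers, l2, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(layers):
            for key, g in layer.grads.items():
                if key in layer.weight_keys and l2:
                    g = g + l2 * layer.params[key]
                m = self.m.setdefault((i, key), np.zeros_like(g))
                v = self.v.setdefault((i, key), np.zeros_like(g))
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                layer.params[key] -= lr * mhat / (np.sqrt(vhat) + self.eps)


class _RMSProp:
    def __init__(self, decay, eps):
        self.decay, self.eps, self.v = decay, eps, {}

    def step(self, layers, l2, lr):
        for i, layer in enumerate(layers):
            for key, g in layer.grads.items():
                if key in layer.weight_keys and l2:
                    g = g + l2 * layer.params[key]
                v = self.v.setdefault((i, key), np.zeros_like(g))
                v += (1 - self.decay) * (g * g - v)
                layer.params[key] -= lr * g / (np.sqrt(v) + self.eps)


def _make_optimizer(config: TrainConfig):
    if config.optimizer == "adam":
        return _Adam(config.adam_beta1, config.adam_decay, config.adam_epsilon)
    if config.optimizer == "rmsp":
        return _RMSProp(config.rmsp_decay, config.adam_epsilon)
    return _SGDMomentum(config.sgd_momentum)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def build(arch: List[LayerSpec], seed: int = 0) -> CNNModel:
    """Instantiate an untrained, seeded model from a layer chain."""
    return CNNModel(arch, seed=seed)


def train(model: CNNModel, images, labels, val_images=None, val_labels=None,
          config: TrainConfig = TrainConfig()) -> CNNModel:
    """Train ``model`` in place (see :meth:`CNNModel.fit`) and return it."""
    return model.fit(images, labels, val_images, val_labels, config)


def predict(model: CNNModel, images):
    """Per-image class probabilities and hard labels (ties -> first class)."""
    return model.predict(images)
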