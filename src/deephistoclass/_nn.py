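"""Minimal, fully deterministic numpy neural-network engine.

Implements exactly what the hybrid classifier needs: 3x3 same-padding
convolutions (im2col), ReLU, 2x2 max pooling, global average pooling, dense
layers with optional Bernoulli drop-weights masks, a numerically stable
sigmoid/binary-cross-entropy loss, and the adaptive-moment optimizer with
maximum-of-past-variance correction (AMSGrad).  All randomness flows through
an explicit ``numpy.random.Generator``; repeated runs with the same seed are
bit-identical on a fixed BLAS configuration.

Drop-weights: each fully connected weight matrix is multiplied elementwise
by an independent Bernoulli(1-rate) mask rescaled by 1/(1-rate), so the
masked weight equals the unmasked weight in expectation.  Masks are
resampled per training batch and per stochastic inference pass; keeping them
active at test time realizes Monte-Carlo variational inference over the head
weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, TrainingError


def he_uniform(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def sample_drop_weights_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(1-rate) keep mask scaled by 1/(1-rate) (mean-preserving)."""
    if not 0.0 <= rate < 1.0:
        raise ConfigError(f"drop rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(np.float64) / keep


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Mean per-label binary cross-entropy, computed stably from logits."""
    return float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))


# ---------------------------------------------------------------------------
# layers

class Conv2D:
    """3x3 (or kxk) same-padding convolution on NHWC tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        fan_in = k * k * c_in
        self.W = he_uniform((k * k * c_in, c_out), fan_in, rng)
        self.b = np.zeros(c_out)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # N,H,W,C,k,k -> N,H,W,k,k,C
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(n * h * w, -1)
        out = cols @ self.W + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray):
        cols, xshape = self._cache
        n, h, w, c = xshape
        d2 = dout.reshape(n * h * w, -1)
        self.dW = cols.T @ d2
        self.db = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(n, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2 (even input sides required)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            self._cache = (xr, out, x.shape)
        return out

    def backward(self, dout):
        xr, out, xshape = self._cache
        mask = xr == out[:, :, None, :, None, :]
        # split gradient equally among ties (rare with continuous activations)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dout[:, :, None, :, None, :] / counts)
        return dxr.reshape(xshape)


class GlobalAvgPool:
    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).copy()


class Dense:
    """Fully connected layer; an optional drop-weights mask gates ``W``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = he_uniform((d_in, d_out), d_in, rng)
        self.b = np.zeros(d_out)
        self._cache = None

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        Wm = self.W if mask is None else self.W * mask
        if train:
            self._cache = (x, mask)
        return x @ Wm + self.b

    def backward(self, dout: np.ndarray):
        x, mask = self._cache
        dW = x.T @ dout
        if mask is not None:
            dW *= mask
        self.dW = dW
        self.db = dout.sum(axis=0)
        Wm = self.W if mask is None else self.W * mask
        return dout @ Wm.T


# ---------------------------------------------------------------------------
# the hybrid network

_BACKBONES = {
    # (channel plan per block; a block = n conv layers then one 2x2 pool)
    "small_cnn": [(16,), (32,), (64,)],
    "vgg19_like": [(64, 64), (128, 128), (256, 256, 256, 256),
                   (512, 512, 512, 512), (512, 512, 512, 512)],
}


class HybridNet:
    """Convolutional trunk + drop-weights fully connected head.

    The trunk maps an NHWC image batch to a ``cnn_feature_dim``-long vector
    (global average pooling followed by a learned projection).  The head
    consumes the hybrid vector (CNN features first, reduced handcrafted
    features second) through drop-weights dense layers and a per-label
    sigmoid output.
    """

    def __init__(self, config, handcrafted_dim: int, rng: np.random.Generator):
        if config.backbone not in _BACKBONES:
            raise ConfigError(f"unknown backbone {config.backbone!r}")
        side = config.image_side
        if side % (2 ** len(_BACKBONES[config.backbone])) != 0:
            raise ConfigError(
                f"image side {side} is not divisible by the backbone's "
                f"pooling factor")
        self.config = config
        self.handcrafted_dim = int(handcrafted_dim)
        self.trunk: list = []
        c_prev = 3
        for block in _BACKBONES[config.backbone]:
            for c_out in block:
                self.trunk.append(Conv2D(c_prev, c_out, 3, rng))
                self.trunk.append(ReLU())
                c_prev = c_out
            self.trunk.append(MaxPool2())
        self.trunk.append(GlobalAvgPool())
        self.proj = Dense(c_prev, config.cnn_feature_dim, rng)
        self.proj_relu = ReLU()
        self.head: list[Dense] = []
        d_prev = config.cnn_feature_dim + self.handcrafted_dim
        for width in config.fc_layer_sizes:
            self.head.append(Dense(d_prev, width, rng))
            d_prev = width
        self.head.append(Dense(d_prev, config.n_labels, rng))

    # ---- forward ----------------------------------------------------------
    def trunk_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.trunk:
            h = layer.forward(h, train=train)
        h = self.proj.forward(h, train=train)
        return self.proj_relu.forward(h, train=train)

    def head_logits(self, hybrid: np.ndarray, masks=None,
                    train: bool = False) -> np.ndarray:
        h = hybrid
        for i, layer in enumerate(self.head):
            m = None if masks is None else masks[i]
            h = layer.forward(h, mask=m, train=train)
            if i < len(self.head) - 1:
                h = np.maximum(h, 0.0) if not train else self._head_relu(i, h)
        return h

    def _head_relu(self, i, h):
        if not hasattr(self, "_head_relus") or len(self._head_relus) != len(self.head) - 1:
            self._head_relus = [ReLU() for _ in range(len(self.head) - 1)]
        return self._head_relus[i].forward(h, train=True)

    def sample_head_masks(self, rng: np.random.Generator):
        rate = self.config.drop_weight_rate
        return [sample_drop_weights_mask(layer.W.shape, rate, rng)
                for layer in self.head]

    def forward_probs(self, x: np.ndarray, hc: np.ndarray,
                      masks=None) -> np.ndarray:
        feats = self.trunk_features(x)
        hybrid = np.concatenate([feats, hc], axis=1)
        return sigmoid(self.head_logits(hybrid, masks=masks))

    # ---- backward ---------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> None:
        h = dlogits
        for i in range(len(self.head) - 1, -1, -1):
            if i < len(self.head) - 1:
                h = self._head_relus[i].backward(h)
            h = self.head[i].backward(h)
        dcnn = h[:, : self.config.cnn_feature_dim]
        dcnn = self.proj_relu.backward(dcnn)
        dcnn = self.proj.backward(dcnn)
        for layer in reversed(self.trunk):
            dcnn = layer.backward(dcnn)

    # ---- parameter access -------------------------------------------------
    def parameters(self):
        out = []
        for layer in self.trunk + [self.proj] + self.head:
            if isinstance(layer, (Conv2D, Dense)):
                out.append(layer)
        return out

    def get_state(self) -> dict:
        state = {}
        for i, layer in enumerate(self.parameters()):
            state[f"W{i}"] = layer.W.copy()
            state[f"b{i}"] = layer.b.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, layer in enumerate(self.parameters()):
            layer.W = state[f"W{i}"].copy()
            layer.b = state[f"b{i}"].copy()


class AMSGrad:
    """Adam with the maximum-of-past-second-moment correction."""

    def __init__(self, layers, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(a) for l in layers for a in (l.W, l.b)]
        self.v = [np.zeros_like(a) for l in layers for a in (l.W, l.b)]
        self.vhat = [np.zeros_like(a) for l in layers for a in (l.W, l.b)]

    def step(self, weight_decay: float = 0.0) -> None:
        self.t += 1
        # both bias corrections folded into the step size
        lr_t = self.lr * np.sqrt(1 - self.beta2 ** self.t) \
            / (1 - self.beta1 ** self.t)
        i = 0
        for layer in self.layers:
            for attr, gattr in (("W", "dW"), ("b", "db")):
                p = getattr(layer, attr)
                g = getattr(layer, gattr)
                if weight_decay and attr == "W":
                    g = g + weight_decay * p
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                p -= lr_t * self.m[i] / (np.sqrt(self.vhat[i]) + self.eps)
                i += 1


# ---------------------------------------------------------------------------
# training

def normalize_images(pixels: np.ndarray) -> np.ndarray:
    """uint8 NHWC -> centered float input in [-0.5, 0.5]."""
    return pixels.astype(np.float64) / 255.0 - 0.5


def train_network(net: HybridNet, X_train, HC_train, Y_train,
                  X_val, HC_val, Y_val, config,
                  rng: np.random.Generator,
                  progress: bool = False):
    """Mini-batch AMSGrad training with best-on-validation checkpointing.

    Returns ``(best_state, log)`` where ``log`` is a list of per-epoch dicts
    (epoch, loss, val_accuracy).  Validation accuracy is the mean per-label
    accuracy at probability threshold 0.5 with the expectation (mask-free)
    forward pass.
    """
    n = X_train.shape[0]
    if n == 0 or X_val.shape[0] == 0:
        raise TrainingError("empty training or validation split")
    opt = AMSGrad(net.parameters(), lr=config.learning_rate)
    wd = config.weight_decay if config.weight_decay_mode == "l2" else 0.0
    log = []
    best_acc = -np.inf
    best_state = net.get_state()
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        lr_scale = 1.0
        if config.weight_decay_mode == "lr_decay":
            lr_scale = 1.0 / (1.0 + config.weight_decay * (epoch - 1))
        opt.lr = config.learning_rate * lr_scale
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = X_train[idx]
            if getattr(config, "augment", False):
                # random dihedral transform: tissue orientation is arbitrary
                k = int(rng.integers(4))
                flip = bool(rng.integers(2))
                xb = np.rot90(xb, k, axes=(1, 2))
                if flip:
                    xb = xb[:, :, ::-1]
                xb = np.ascontiguousarray(xb)
            hcb = HC_train[idx]
            yb = Y_train[idx].astype(np.float64)
            masks = net.sample_head_masks(rng)
            feats = net.trunk_features(xb, train=True)
            hybrid = np.concatenate([feats, hcb], axis=1)
            logits = net.head_logits(hybrid, masks=masks, train=True)
            loss = bce_from_logits(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"loss became non-finite at epoch {epoch} "
                    f"(batch starting at {start}); lower the learning rate")
            epoch_loss += loss * len(idx)
            dlogits = (sigmoid(logits) - yb) / logits.size
            net.backward(dlogits)
            opt.step(weight_decay=wd)
        epoch_loss /= n
        val_probs = net.forward_probs(X_val, HC_val, masks=None)
        val_acc = float(np.mean((val_probs >= 0.5) == (Y_val >= 0.5)))
        log.append({"epoch": epoch, "loss": epoch_loss, "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = net.get_state()
        if progress:
            print(f"  epoch {epoch:3d}  loss {epoch_loss:.4f}  "
                  f"val_acc {val_acc:.4f}")
    net.set_state(best_state)
    return best_state, log


def mc_predict_probs(net: HybridNet, X, HC, T: int,
                     rng: np.random.Generator) -> np.ndarray:
    """T stochastic forward passes; returns an (n, T, C) probability array.

    The deterministic trunk is evaluated once; only the drop-weights head is
    resampled per pass (handcrafted and CNN features are deterministic).
    """
    if T < 1:
        raise ConfigError(f"T must be >= 1, got {T}")
    feats = net.trunk_features(X)
    hybrid = np.concatenate([feats, HC], axis=1)
    n, C = X.shape[0], net.config.n_labels
    out = np.empty((n, T, C))
    for t in range(T):
        masks = (net.sample_head_masks(rng)
                 if net.config.drop_weight_rate > 0 else None)
        out[:, t, :] = sigmoid(net.head_logits(hybrid, masks=masks))
    return out
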