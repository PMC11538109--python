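"""Compact NumPy neural-network primitives and the two model families used
by the package: a residual CNN binary classifier (invasion calling) and a
U-Net-style encoder/decoder with separable-convolution blocks (vessel
segmentation).

Layers implement explicit ``forward``/``backward`` passes on (N, C, H, W)
float32 arrays; stride-1 "same" convolutions are computed with
``sliding_window_view`` + ``einsum``, and their input gradients as the
same convolution with a flipped kernel.  Optimisation is Adam on
binary-cross-entropy-with-logits.  All randomness (initialisation, batch
sampling) flows through an explicit ``numpy.random.Generator`` so
training is bit-reproducible under a fixed seed.

These are desk-scale networks: a handful of channels and 32-96 px
inputs, sized to train in seconds-to-minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N,C,H,W,k,k) same-padded sliding windows."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    return sliding_window_view(xp, (k, k), axis=(2, 3))


class Conv2D:
    """Stride-1 same-padding 2D convolution (cross-correlation)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        self.w = Param(_he(rng, (cout, cin, k, k), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._win = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = _windows(x, self.k)
        return np.einsum("nchwij,ocij->nohw", self._win, self.w.value, optimize=True) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("nchwij,nohw->ocij", self._win, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dwin = _windows(dout, self.k)
        wflip = self.w.value[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", dwin, wflip, optimize=True)


class DepthwiseConv2D:
    """Per-channel stride-1 same-padding convolution."""

    def __init__(self, c: int, k: int, rng: np.random.Generator):
        self.k = k
        self.w = Param(_he(rng, (c, k, k), k * k))
        self.b = Param(np.zeros(c, dtype=np.float32))
        self._win = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = _windows(x, self.k)
        return np.einsum("nchwij,cij->nchw", self._win, self.w.value, optimize=True) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("nchwij,nchw->cij", self._win, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dwin = _windows(dout, self.k)
        wflip = self.w.value[:, ::-1, ::-1]
        return np.einsum("nchwij,cij->nchw", dwin, wflip, optimize=True)


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(_he(rng, (cin, cout), cin))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; inputs must have even H and W."""

    def __init__(self):
        self._onehot = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = np.argmax(xr, axis=-1)
        self._onehot = np.eye(4, dtype=np.float32)[idx]
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = dout[..., None] * self._onehot
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy; returns (loss, dlogits).

    ``pos_weight`` up-weights positive targets — the usual remedy for
    thin-structure segmentation, where a constant all-background
    prediction is otherwise a strong local minimum.
    """
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    w = 1.0 + (pos_weight - 1.0) * t
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))) * w
    p = sigmoid(z)
    return float(loss.mean()), (w * (p - t) / z.size).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ResBlock:
    """y = relu(x + conv(relu(conv(x)))), channel-preserving."""

    def __init__(self, c: int, k: int, rng: np.random.Generator):
        self.c1 = Conv2D(c, c, k, rng)
        self.r1 = ReLU()
        self.c2 = Conv2D(c, c, k, rng)
        self.rout = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.r1.forward(self.c1.forward(x))
        return self.rout.forward(x + self.c2.forward(h))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.rout.backward(dout)
        dh = self.c2.backward(d)
        dx = self.c1.backward(self.r1.backward(dh))
        return d + dx


class ResidualCNN:
    """Small residual CNN for binary classification of grayscale tiles.

    Stages of channel-preserving residual blocks separated by 2x max
    pooling, then global average pooling and a dense logit head.  The
    reference configuration of the method this emulates is a 50-layer
    residual network; the desk-scale default is stages (8, 16) with one
    block each, which trains in seconds and suffices for behavioural
    (fixture-accuracy) evaluation.
    """

    def __init__(self, input_size: int = 32, stage_channels: tuple[int, ...] = (8, 16),
                 blocks_per_stage: int = 1, k: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.stage_channels = tuple(stage_channels)
        self.layers: list = []
        cin = 1
        for si, c in enumerate(self.stage_channels):
            self.layers.append(Conv2D(cin, c, k, rng))
            self.layers.append(ReLU())
            for _ in range(blocks_per_stage):
                self.layers.append(ResBlock(c, k, rng))
            if si < len(self.stage_channels) - 1:
                self.layers.append(MaxPool2())
            cin = c
        self.head = Dense(self.stage_channels[-1], 1, rng)

    def params(self):
        ps = []
        for layer in self.layers:
            ps.extend(layer.params())
        return ps + self.head.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        self._gap_shape = h.shape
        pooled = h.mean(axis=(2, 3))
        return self.head.forward(pooled)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None])
        n, c, h, w = self._gap_shape
        dh = np.broadcast_to(d[:, :, None, None], self._gap_shape) / (h * w)
        dh = np.ascontiguousarray(dh, dtype=np.float32)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x))


class SepConvBlock:
    """Two (depthwise 3x3 -> pointwise 1x1 -> ReLU) units, Xception style."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.d1 = DepthwiseConv2D(cin, 3, rng)
        self.p1 = Conv2D(cin, cout, 1, rng)
        self.r1 = ReLU()
        self.d2 = DepthwiseConv2D(cout, 3, rng)
        self.p2 = Conv2D(cout, cout, 1, rng)
        self.r2 = ReLU()
        self._seq = [self.d1, self.p1, self.r1, self.d2, self.p2, self.r2]

    def params(self):
        ps = []
        for layer in self._seq:
            ps.extend(layer.params())
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self._seq:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self._seq):
            dout = layer.backward(dout)
        return dout


class UNet:
    """U-Net-style encoder/decoder with separable-convolution blocks.

    ``filters`` gives the per-level channel counts (increasing); the
    spatial size halves per level down and doubles back up, with skip
    concatenation at each level.  Output is a single logit map the size
    of the input; ``predict_proba`` applies the sigmoid.  Inputs must be
    divisible by ``2 ** (len(filters) - 1)``.
    """

    def __init__(self, filters: tuple[int, ...] = (8, 16, 32, 64), input_size: int = 64, seed: int = 0):
        if any(b <= a for a, b in zip(filters, filters[1:])):
            raise ValueError("filter counts must be strictly increasing")
        rng = np.random.default_rng(seed)
        self.filters = tuple(filters)
        self.input_size = input_size
        depth = len(filters)
        self.enc = []
        cin = 1
        for f in filters:
            self.enc.append(SepConvBlock(cin, f, rng))
            cin = f
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = [Upsample2() for _ in range(depth - 1)]
        # decoder level i (top = 0) consumes cat(skip_i, upsampled deeper features)
        self.dec = []
        for i in range(depth - 2, -1, -1):
            self.dec.append(SepConvBlock(filters[i] + filters[i + 1], filters[i], rng))
        self.out_conv = Conv2D(filters[0], 1, 1, rng)

    def params(self):
        ps = []
        for block in self.enc + self.dec:
            ps.extend(block.params())
        return ps + self.out_conv.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block.forward(h)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for j, block in enumerate(self.dec):
            level = len(self.enc) - 2 - j
            up = self.ups[level].forward(h)
            h = block.forward(np.concatenate([skips[level], up], axis=1))
        return self.out_conv.forward(h)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out_conv.backward(np.ascontiguousarray(dlogits[:, None], dtype=np.float32))
        dskips = [None] * len(self._skip_channels)
        for j in range(len(self.dec) - 1, -1, -1):
            level = len(self.enc) - 2 - j
            dcat = self.dec[j].backward(d)
            cs = self._skip_channels[level]
            dskip, dup = dcat[:, :cs], dcat[:, cs:]
            dskips[level] = dskip if dskips[level] is None else dskips[level] + dskip
            d = self.ups[level].backward(np.ascontiguousarray(dup))
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.enc) - 1:
                d = self.pools[i].backward(d) + dskips[i]
            d = self.enc[i].backward(np.ascontiguousarray(d))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x))


def train_binary(
    model,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    steps_per_epoch: int,
    lr: float,
    seed: int,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Adam/BCE training loop shared by both model families.

    Each step samples ``batch_size`` items at random (with replacement)
    from the training set.  Returns a history dict with per-epoch train
    loss and, when a validation split is given, validation loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=lr)
    history: dict = {"train_loss": [], "val_loss": []}
    for _ in range(epochs):
        losses = []
        for _ in range(steps_per_epoch):
            idx = rng.integers(0, x.shape[0], size=batch_size)
            logits = model.forward(x[idx])
            loss, dlogits = bce_with_logits(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if x_val is not None:
            vlogits = model.forward(x_val)
            vloss, _ = bce_with_logits(vlogits, y_val)
            history["val_loss"].append(vloss)
    return history
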