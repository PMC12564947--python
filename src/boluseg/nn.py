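"""Minimal CPU neural-network layers used by the reconstruction autoencoder.

Implements exactly the pieces the segmentation model needs — same-padding 3x3
convolutions (im2col + GEMM), batch normalization, ReLU, dropout, 2x2 max
pooling, kernel-2 stride-2 transpose convolutions, and a sigmoid head — with
hand-written backward passes, an Adam optimizer and a reduce-on-plateau
learning-rate scheduler.  Everything runs in float32 on numpy arrays in
channel-last (N, H, W, C) layout, which keeps the im2col unfolding a set of
contiguous block copies, and is bit-reproducible given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "MaxPool2d",
    "ConvTranspose2d",
    "Sigmoid",
    "Autoencoder",
    "Adam",
    "ReduceLROnPlateau",
]


def _im2col(x: np.ndarray, k: int, pad: int, pad_mode: str = "zeros") -> np.ndarray:
    """Unfold k x k patches of ``x`` (N,H,W,C) into a (N*H*W, k*k*C) matrix.

    Row ordering of each patch is (ky, kx, channel), matching the weight
    layout ``(k, k, C_in, C_out)`` used by :class:`Conv2d`.
    """
    n, h, w, c = x.shape
    spec = ((0, 0), (pad, pad), (pad, pad), (0, 0))
    xp = np.pad(x, spec) if pad_mode == "zeros" else np.pad(x, spec, mode="wrap")
    cols = np.empty((n, h, w, k * k, c), dtype=x.dtype)
    for ky in range(k):
        for kx in range(k):
            cols[:, :, :, ky * k + kx, :] = xp[:, ky : ky + h, kx : kx + w, :]
    return cols.reshape(n * h * w, k * k * c)


class Layer:
    """Base class: parameterized layers expose ``params`` and matching ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1, same-padding 2-D convolution with bias; weights (k,k,Cin,Cout).

    ``pad_mode`` "zeros" is the conventional choice; "circular" wraps the
    image on a torus, which removes the absolute-position cue that zero
    borders otherwise leak into deep features.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        pad_mode: str = "zeros",
    ):
        super().__init__()
        if pad_mode not in ("zeros", "circular"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        self.pad_mode = pad_mode
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, std, (kernel, kernel, in_channels, out_channels)).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x, training):
        n, h, w, _ = x.shape
        cols = _im2col(x, self.kernel, self.pad, self.pad_mode)
        if training:
            self._shape = x.shape
            self._cols = cols  # reused for the weight gradient in backward
        out = cols @ self.params["W"].reshape(-1, self.out_channels) + self.params["b"]
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, dout):
        n, h, w, _ = self._shape
        k = self.kernel
        dmat = dout.reshape(n * h * w, self.out_channels)
        cols = self._cols
        self._cols = None
        self.grads["W"] = (cols.T @ dmat).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        # gradient w.r.t. the input of a same-padding stride-1 conv is a conv
        # with spatially flipped kernels and swapped channel roles (the
        # adjoint of a circular conv is likewise circular)
        w_flip = np.ascontiguousarray(self.params["W"][::-1, ::-1].transpose(0, 1, 3, 2))
        dcols = _im2col(dout, k, self.pad, self.pad_mode)
        dx = dcols @ w_flip.reshape(-1, self.in_channels)
        return dx.reshape(n, h, w, self.in_channels)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
            inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat = (x - mu.astype(np.float32)) * inv_std
            self._cache = (xhat, inv_std)
            return self.params["gamma"] * xhat + self.params["beta"]
        inv_std = (1.0 / np.sqrt(self.running_var + self.eps)).astype(np.float32)
        xhat = (x - self.running_mean) * inv_std
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv_std = self._cache
        n, h, w, _ = dout.shape
        m = n * h * w
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.params["gamma"]
        s1 = dxhat.sum(axis=(0, 1, 2), dtype=np.float32)
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2), dtype=np.float32)
        return (inv_std / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout):
        return np.where(self._mask, dout, np.float32(0.0))


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first maximum."""

    def forward(self, x, training):
        self._x = x
        a = x[:, ::2, ::2]
        b = x[:, ::2, 1::2]
        c = x[:, 1::2, ::2]
        d = x[:, 1::2, 1::2]
        y = np.maximum(np.maximum(a, b), np.maximum(c, d))
        self._y = y
        return y

    def backward(self, dout):
        x, y = self._x, self._y
        dx = np.zeros_like(x)
        taken = np.zeros(y.shape, dtype=bool)
        for dy_, dx_ in ((0, 0), (0, 1), (1, 0), (1, 1)):
            sl = (slice(None), slice(dy_, None, 2), slice(dx_, None, 2))
            hit = (x[sl] == y) & ~taken
            dx[sl] = np.where(hit, dout, np.float32(0.0))
            taken |= hit
        return dx


class ConvTranspose2d(Layer):
    """Kernel-2, stride-2 transpose convolution (exact 2x upsampling); weights (Cin,2,2,Cout)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        std = np.sqrt(2.0 / (in_channels * 4))
        self.params["W"] = rng.normal(0.0, std, (in_channels, 2, 2, out_channels)).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)

    def forward(self, x, training):
        self._x = x
        n, h, w, ci = x.shape
        co = self.out_channels
        y = x.reshape(-1, ci) @ self.params["W"].reshape(ci, 4 * co)
        y = y.reshape(n, h, w, 2, 2, co).transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, co)
        return y + self.params["b"]

    def backward(self, dout):
        x = self._x
        n, h, w, ci = x.shape
        co = self.out_channels
        d6 = np.ascontiguousarray(
            dout.reshape(n, h, 2, w, 2, co).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(n * h * w, 4 * co)
        xmat = x.reshape(-1, ci)
        self.grads["W"] = (xmat.T @ d6).reshape(self.params["W"].shape)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dx = d6 @ self.params["W"].reshape(ci, 4 * co).T
        return dx.reshape(n, h, w, ci)


class Sigmoid(Layer):
    def forward(self, x, training):
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class _DecoderLevel:
    """Transpose-conv upsample, concat the matching-resolution encoder map, merge."""

    def __init__(self, in_c: int, up_c: int, skip_c: int, out_c: int, kernel: int, rng, pad_mode="zeros"):
        self.up = ConvTranspose2d(in_c, up_c, rng)
        self.merge = Conv2d(up_c + skip_c, out_c, kernel, rng, pad_mode)
        self.bn = BatchNorm2d(out_c)
        self.act = ReLU()

    def layers(self):
        return [self.up, self.merge, self.bn, self.act]

    def forward(self, x, skip, training):
        u = self.up.forward(x, training)
        z = np.concatenate([u, skip], axis=-1)
        return self.act.forward(self.bn.forward(self.merge.forward(z, training), training), training)

    def backward(self, dout):
        dz = self.merge.backward(self.bn.backward(self.act.backward(dout)))
        up_c = self.up.out_channels
        du, dskip = dz[..., :up_c], dz[..., up_c:]
        return self.up.backward(np.ascontiguousarray(du)), np.ascontiguousarray(dskip)


class Autoencoder:
    """Convolutional encoder-decoder with skip connections and a sigmoid head.

    Encoder: three blocks of [conv 3x3 -> batchnorm -> ReLU (-> dropout in the
    first block)] each followed by 2x2 max pooling.  Decoder mirrors the
    encoder with transpose-conv upsampling and concatenation of the encoder
    feature map at the matching resolution, followed by a 3x3 merge
    convolution, batchnorm and ReLU per level.  Inputs are (N, H, W, C) with
    spatial size divisible by 8; outputs are ``out_channels`` maps in (0,1).
    """

    def __init__(
        self,
        in_channels: int,
        widths: tuple[int, int, int] = (64, 128, 256),
        out_channels: int = 3,
        kernel: int = 3,
        dropout_rate: float = 0.1,
        seed: int = 0,
        pad_mode: str = "zeros",
    ):
        self.in_channels = in_channels
        self.widths = tuple(int(w) for w in widths)
        self.out_channels = out_channels
        self.kernel = kernel
        self.dropout_rate = dropout_rate
        self.seed = seed
        self.pad_mode = pad_mode
        rng = np.random.default_rng(seed)
        w1, w2, w3 = self.widths

        self.enc = []
        for i, (ci, co) in enumerate([(in_channels, w1), (w1, w2), (w2, w3)]):
            block = {"conv": Conv2d(ci, co, kernel, rng, pad_mode), "bn": BatchNorm2d(co), "act": ReLU()}
            if i == 0 and dropout_rate > 0:
                block["drop"] = Dropout(dropout_rate, rng)
            block["pool"] = MaxPool2d()
            self.enc.append(block)

        self.dec = [
            _DecoderLevel(w3, w2, w3, w2, kernel, rng, pad_mode),
            _DecoderLevel(w2, w1, w2, w1, kernel, rng, pad_mode),
            _DecoderLevel(w1, w1, w1, w1, kernel, rng, pad_mode),
        ]
        self.head = Conv2d(w1, out_channels, kernel, rng, pad_mode)
        self.out_act = Sigmoid()

    # -- plumbing ----------------------------------------------------------
    def _layers(self) -> list[Layer]:
        out: list[Layer] = []
        for block in self.enc:
            out.extend(block.values())
        for lvl in self.dec:
            out.extend(lvl.layers())
        out.extend([self.head, self.out_act])
        return out

    def parameters(self):
        """Yield (layer, name, array) triples for every trainable tensor."""
        for layer in self._layers():
            for name in layer.params:
                yield layer, name, layer.params[name]

    def count_parameters(self) -> int:
        return int(sum(p.size for _, _, p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._layers()):
            for name, p in layer.params.items():
                state[f"layer{i}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for name in layer.params:
                layer.params[name] = state[f"layer{i}.{name}"].copy()
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"layer{i}.running_mean"].copy()
                layer.running_var = state[f"layer{i}.running_var"].copy()

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[-1] != self.in_channels:
            raise ValueError(f"expected (N,H,W,{self.in_channels}) input, got shape {x.shape}")
        if x.shape[1] % 8 or x.shape[2] % 8:
            raise ValueError(
                f"spatial size {x.shape[1]}x{x.shape[2]} must be divisible by 8 "
                "(three 2x2 pooling stages)"
            )
        return np.ascontiguousarray(x, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(x)
        skips = []
        for block in self.enc:
            x = block["conv"].forward(x, training)
            x = block["bn"].forward(x, training)
            x = block["act"].forward(x, training)
            if "drop" in block:
                x = block["drop"].forward(x, training)
            skips.append(x)
            x = block["pool"].forward(x, training)
        for lvl, skip in zip(self.dec, reversed(skips)):
            x = lvl.forward(x, skip, training)
        return self.out_act.forward(self.head.forward(x, training), training)

    def backward(self, dout: np.ndarray) -> None:
        d = self.head.backward(self.out_act.backward(dout))
        dskips = []
        for lvl in reversed(self.dec):
            d, dskip = lvl.backward(d)
            dskips.append(dskip)
        dskips.reverse()  # dskips[i] pairs with encoder block 3-i
        for block, dskip in zip(reversed(self.enc), dskips):
            d = block["pool"].backward(d)
            d = d + dskip
            if "drop" in block:
                d = block["drop"].backward(d)
            d = block["act"].backward(d)
            d = block["bn"].backward(d)
            d = block["conv"].backward(d)

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Evaluation-mode reconstruction (running BN statistics, no dropout)."""
        x = self._check_input(x)
        chunks = [self.forward(x[i : i + batch_size], training=False) for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)


class Adam:
    """Adam with the standard (0.9, 0.999) moments and no weight decay."""

    def __init__(self, model: Autoencoder, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for key, (layer, name, p) in enumerate(self.model.parameters()):
            g = layer.grads[name].astype(np.float32)
            m = self._m.get(key)
            if m is None:
                m = np.zeros_like(p)
                self._m[key] = m
                self._v[key] = np.zeros_like(p)
            v = self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= np.float32(self.lr) * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, monitored: float) -> None:
        if monitored < self.best:
            self.best = monitored
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr *= self.factor
                self.bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr
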