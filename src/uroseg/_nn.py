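"""Minimal N-dimensional residual U-Net on numpy.

A small, self-contained convolutional network with hand-written
backpropagation, sufficient to train the reduced segmentation models this
package uses on synthetic data.  Works for 2D images and 3D volumes
(``rank`` parameter).  Everything is float32 and fully deterministic for a
fixed seed (pure numpy, single threaded math).

Layout conventions: tensors are ``(N, C, *spatial)``.  Convolutions are
3^rank kernels with "same" padding, implemented as a loop over kernel
offsets with one batched GEMM per offset (no im2col materialization).
The decoder upsamples by nearest-neighbor repetition followed by a
convolution, a standard transposed-convolution substitute.
"""

from __future__ import annotations

import itertools

import numpy as np

F4 = np.float32


# ---------------------------------------------------------------------------
# layers


class Conv:
    """k^rank convolution, stride 1 or 2, same padding, He init.

    Implemented as im2col + one GEMM; the column matrix is rebuilt during
    backward from the cached padded input to keep peak memory low.
    """

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 k: int = 3, stride: int = 1, rank: int = 2):
        fan_in = cin * k ** rank
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (cout, cin) + (k,) * rank).astype(F4)
        self.b = np.zeros(cout, dtype=F4)
        self.k, self.stride, self.rank = k, stride, rank
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self, "W", "dW"), (self, "b", "db")]

    def _offsets(self):
        return itertools.product(range(self.k), repeat=self.rank)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, rank = self.k, self.stride, self.rank
        pad = k // 2
        n, cin = x.shape[:2]
        cout = self.W.shape[0]
        xpad = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * rank) if pad else x
        out_sp = tuple((d + 2 * pad - k) // s + 1 for d in x.shape[2:])
        L = int(np.prod(out_sp))
        out = np.zeros((n, cout, L), dtype=F4)
        for o in self._offsets():
            sl = xpad[(slice(None), slice(None))
                      + tuple(slice(oi, oi + s * d, s)
                              for oi, d in zip(o, out_sp))]
            out += self.W[(slice(None), slice(None)) + o] @ \
                sl.reshape(n, cin, L)
        out += self.b[None, :, None]
        if train:
            self._cache = (xpad, x.shape, out_sp)
        return out.reshape((n, cout) + out_sp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xpad, x_shape, out_sp = self._cache
        k, s, rank = self.k, self.stride, self.rank
        pad = k // 2
        n, cin = x_shape[:2]
        cout = self.W.shape[0]
        L = int(np.prod(out_sp))
        dflat = dout.reshape(n, cout, L)
        self.db[:] = dflat.sum(axis=(0, 2))
        dxpad = np.zeros_like(xpad)
        for o in self._offsets():
            window = (slice(None), slice(None)) + tuple(
                slice(oi, oi + s * d, s) for oi, d in zip(o, out_sp))
            sl = xpad[window].reshape(n, cin, L)
            wo = (slice(None), slice(None)) + o
            self.dW[wo] = np.einsum("nfl,ncl->fc", dflat, sl, optimize=True)
            dxpad[window] += (self.W[wo].T @ dflat).reshape((n, cin) + out_sp)
        if pad:
            core = (slice(None), slice(None)) + (slice(pad, -pad),) * rank
            return dxpad[core]
        return dxpad


class InstanceNorm:
    """Per-sample, per-channel normalization over spatial axes."""

    eps = 1e-5

    def __init__(self, channels: int):
        self.gamma = np.ones(channels, dtype=F4)
        self.beta = np.zeros(channels, dtype=F4)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def parameters(self):
        return [(self, "gamma", "dgamma"), (self, "beta", "dbeta")]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(2, x.ndim))
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        shape = (1, -1) + (1,) * (x.ndim - 2)
        out = self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)
        if train:
            self._cache = (xhat, inv, axes, shape)
        return out.astype(F4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        m = np.prod([dout.shape[a] for a in axes])
        self.dgamma[:] = (dout * xhat).sum(axis=(0,) + axes)
        self.dbeta[:] = dout.sum(axis=(0,) + axes)
        dxhat = dout * self.gamma.reshape(shape)
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) * inv
        return dx.astype(F4)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Elementwise inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(F4) / F4(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _upsample(x: np.ndarray, rank: int) -> np.ndarray:
    for axis in range(2, 2 + rank):
        x = np.repeat(x, 2, axis=axis)
    return x


def _downsample_grad(d: np.ndarray, rank: int) -> np.ndarray:
    """Adjoint of nearest-neighbor x2 upsampling: sum over 2-blocks."""
    for axis in range(2, 2 + rank):
        n = d.shape[axis]
        shape = d.shape[:axis] + (n // 2, 2) + d.shape[axis + 1:]
        d = d.reshape(shape).sum(axis=axis + 1)
    return d


class ResUnit:
    """conv-norm-relu(-dropout)-conv-norm with a (projected) skip."""

    def __init__(self, rng, cin, cout, stride=1, rank=2, dropout=0.0):
        self.conv1 = Conv(rng, cin, cout, 3, stride, rank)
        self.norm1 = InstanceNorm(cout)
        self.act1 = ReLU()
        self.drop = Dropout(dropout, rng)
        self.conv2 = Conv(rng, cout, cout, 3, 1, rank)
        self.norm2 = InstanceNorm(cout)
        self.proj = None
        if cin != cout or stride != 1:
            self.proj = Conv(rng, cin, cout, 1, stride, rank)
        self.act_out = ReLU()

    def parameters(self):
        layers = [self.conv1, self.norm1, self.conv2, self.norm2]
        if self.proj is not None:
            layers.append(self.proj)
        return [p for layer in layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.norm1.forward(h, train)
        h = self.act1.forward(h, train)
        h = self.drop.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.norm2.forward(h, train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.act_out.forward(h + skip, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.act_out.backward(dout)
        dskip = d if self.proj is None else self.proj.backward(d)
        dh = self.norm2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.drop.backward(dh)
        dh = self.act1.backward(dh)
        dh = self.norm1.backward(dh)
        dh = self.conv1.backward(dh)
        return dh + dskip


class UNet:
    """Residual U-Net: stride-2 encoder, nearest-up + conv decoder.

    ``channels`` gives the feature width per resolution level;
    ``residual_units`` is the number of residual units per level.
    The final layer is a 1x1 convolution to a single logit channel.
    """

    def __init__(self, channels=(8, 16, 32), rank=2, residual_units=1,
                 dropout=0.0, seed=0):
        rng = np.random.default_rng(seed)
        self.rank = int(rank)
        self.channels = tuple(int(c) for c in channels)
        levels = len(self.channels)

        def block(cin, cout, stride):
            units = [ResUnit(rng, cin, cout, stride, self.rank, dropout)]
            for _ in range(residual_units - 1):
                units.append(ResUnit(rng, cout, cout, 1, self.rank, dropout))
            return units

        self.enc = [block(1, self.channels[0], 1)]
        for i in range(1, levels):
            self.enc.append(block(self.channels[i - 1], self.channels[i], 2))
        self.dec = []
        for i in reversed(range(levels - 1)):
            self.dec.append(
                block(self.channels[i + 1] + self.channels[i],
                      self.channels[i], 1))
        self.head = Conv(rng, self.channels[0], 1, k=1, stride=1,
                         rank=self.rank)
        # start near the background prior (foreground is ~1% of pixels);
        # skips the long initial phase of suppressing background
        self.head.b[:] = -4.0
        self._skip_channels = list(reversed(self.channels[:-1]))

    def parameters(self):
        out = []
        for blocks in self.enc + self.dec:
            for unit in blocks:
                out.extend(unit.parameters())
        out.extend(self.head.parameters())
        return out

    def state(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy()
                for layer, name, _ in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for (layer, name, _), arr in zip(self.parameters(), arrays):
            getattr(layer, name)[...] = arr

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x.astype(F4)
        skips = []
        for i, blocks in enumerate(self.enc):
            for unit in blocks:
                h = unit.forward(h, train)
            if i < len(self.enc) - 1:
                skips.append(h)
        for blocks, skip in zip(self.dec, reversed(skips)):
            h = _upsample(h, self.rank)
            h = np.concatenate([h, skip], axis=1)
            for unit in blocks:
                h = unit.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for blocks, c_skip in zip(reversed(self.dec),
                                  reversed(self._skip_channels)):
            for unit in reversed(blocks):
                d = unit.backward(d)
            c_up = d.shape[1] - c_skip
            dskips.append(d[:, c_up:])
            d = _downsample_grad(d[:, :c_up], self.rank)
        # dskips were collected shallow-first (level 0 first); encoder levels
        # are walked deep-first, so index from the back
        for i, blocks in enumerate(reversed(self.enc)):
            if i > 0:
                d = d + dskips[len(dskips) - i]
            for unit in reversed(blocks):
                d = unit.backward(d)


# ---------------------------------------------------------------------------
# loss and optimizer


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=F4)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_ce_loss(logits: np.ndarray, target: np.ndarray,
                 eps: float = 1e-5) -> tuple[float, np.ndarray]:
    """Equal-weight soft-Dice + binary cross-entropy, with gradient.

    Dice is computed per sample and averaged; cross-entropy is the mean
    over all elements.  Returns ``(loss, dlogits)``.
    """
    t = target.astype(F4)
    p = sigmoid(logits)
    n = logits.shape[0]
    spatial = tuple(range(1, logits.ndim))

    # stable BCE: softplus(z) - t*z
    z = logits
    softplus = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30))))
    bce = float((softplus - t * z).mean())
    dbce = (p - t) / F4(z.size)

    inter = (p * t).sum(axis=spatial)
    sums = p.sum(axis=spatial) + t.sum(axis=spatial)
    dice = 1.0 - (2.0 * inter + eps) / (sums + eps)
    dice_loss = float(dice.mean())
    num = (2.0 * inter + eps).reshape((n,) + (1,) * (logits.ndim - 1))
    den = (sums + eps).reshape((n,) + (1,) * (logits.ndim - 1))
    ddice_dp = -(2.0 * t * den - num) / den ** 2 / F4(n)
    ddice = ddice_dp * p * (1.0 - p)

    return bce + dice_loss, (dbce + ddice).astype(F4)


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n, _ in params]
        self.v = [np.zeros_like(getattr(l, n)) for l, n, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (layer, name, gname) in enumerate(self.params):
            g = getattr(layer, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.lr * (self.m[i] / b1t)
                      / (np.sqrt(self.v[i] / b2t) + self.eps))
            getattr(layer, name)[...] -= update.astype(F4)
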