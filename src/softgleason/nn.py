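"""Minimal numpy neural-network core for the segmentation model.

A compact, fully deterministic CPU implementation of the pieces the trainer
needs: 3×3/1×1 convolutions (im2col), ReLU, 2×2 max pooling, nearest
upsampling, skip concatenation, softmax, and AdamW with decoupled weight
decay.  The default architecture is a small U-Net: an encoder of strided
(pooled) conv blocks, a bottleneck, and a decoder that upsamples and
concatenates the encoder skips, ending in a 1×1 head and per-pixel softmax.

Arrays are channels-last (N, H, W, C) float64 throughout; determinism on CPU
is exact because every operation is plain numpy.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((n, oh, ow, k * k * c), dtype=x.dtype)
    i = 0
    for dy in range(k):
        for dx in range(k):
            cols[..., i * c : (i + 1) * c] = x[:, dy : dy + oh, dx : dx + ow, :]
            i += 1
    return cols


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    n, h, w, c = shape
    oh, ow = h - k + 1, w - k + 1
    dx = np.zeros(shape, dtype=dcols.dtype)
    i = 0
    for dy in range(k):
        for dxo in range(k):
            dx[:, dy : dy + oh, dxo : dxo + ow, :] += dcols[..., i * c : (i + 1) * c]
            i += 1
    return dx


class Conv:
    """Same-padded k×k convolution with bias."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))
        self.w = Param(rng.normal(0.0, scale, size=(k * k * cin, cout)))
        self.b = Param(np.zeros(cout))
        self.k = k
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        cols = _im2col(xp, self.k) if self.k > 1 else xp
        self._cache = (cols, xp.shape)
        return cols @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape = self._cache
        flat_cols = cols.reshape(-1, cols.shape[-1])
        flat_dy = dy.reshape(-1, dy.shape[-1])
        self.w.grad += flat_cols.T @ flat_dy
        self.b.grad += flat_dy.sum(axis=0)
        dcols = dy @ self.w.value.T
        p = self.k // 2
        if self.k > 1:
            dxp = _col2im(dcols, xp_shape, self.k)
        else:
            dxp = dcols
        return dxp[:, p : xp_shape[1] - p, p : xp_shape[2] - p, :] if p else dxp

    def params(self):
        return [self.w, self.b]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class MaxPool2:
    def forward(self, x):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        r = r.reshape(n, h // 2, w // 2, 4, c)
        self._arg = r.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(r, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        n, h, w, c = self._shape
        dr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dr, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dr = dr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dr.reshape(n, h, w, c)

    def params(self):
        return []


class Upsample2:
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def params(self):
        return []


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient through softmax: dz = p ⊙ (dp − Σ dp·p)."""
    return p * (dp - (dp * p).sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# tiny U-Net
# ---------------------------------------------------------------------------

class _Block:
    """conv3-relu-conv3-relu."""

    def __init__(self, cin, cout, rng):
        self.layers = [Conv(cin, cout, 3, rng), ReLU(), Conv(cout, cout, 3, rng), ReLU()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]


class TinyUNet:
    """Small encoder–decoder segmentation network with skip connections.

    ``depth`` pooling stages halve the spatial size; channel width doubles
    from ``base`` per stage.  The forward pass returns a per-pixel softmax
    distribution with the same spatial shape as the input.
    """

    def __init__(self, in_channels: int, n_classes: int, base: int = 8, depth: int = 2,
                 seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.n_classes = n_classes
        self.enc = []
        cin = in_channels
        ch = base
        for _ in range(depth):
            self.enc.append(_Block(cin, ch, rng))
            cin, ch = ch, ch * 2
        self.bottleneck = _Block(cin, ch, rng)
        self.dec = []
        for i in range(depth):
            skip_ch = ch // 2
            self.dec.append(_Block(ch + skip_ch, skip_ch, rng))
            ch = skip_ch
        self.head = Conv(ch, n_classes, 1, rng)
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = [Upsample2() for _ in range(depth)]

    # -- api -------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[None]
        stride = 2 ** self.depth
        h, w = x.shape[1:3]
        if h % stride or w % stride:
            need_h = (stride - h % stride) % stride
            need_w = (stride - w % stride) % stride
            raise ValueError(
                f"spatial shape {h}x{w} not divisible by encoder stride {stride}; "
                f"pad by ({need_h}, {need_w})"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(skip.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            x = blk.forward(x)
        logits = self.head.forward(x)
        self._probs = softmax(logits)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        if dprobs.ndim == 3:
            dprobs = dprobs[None]
        dy = softmax_backward(self._probs, dprobs)
        dy = self.head.backward(dy)
        dskips = []
        for blk, up, skip_ch in zip(reversed(self.dec), reversed(self.ups),
                                    reversed(self._skip_ch)):
            dy = blk.backward(dy)
            dskip = dy[..., -skip_ch:]
            dy = up.backward(dy[..., :-skip_ch])
            dskips.append(dskip)
        dy = self.bottleneck.backward(dy)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = blk.backward(dy)

    def params(self) -> list[Param]:
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- (de)serialization ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[str(i)]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                  + self.weight_decay * p.value)
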