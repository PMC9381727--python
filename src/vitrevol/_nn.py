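"""Minimal CPU convolutional-network engine for plane segmentation.

A small residual encoder-decoder (U-Net-style: two average-pool downsampling
levels, nearest-neighbor upsampling, additive skip connections, residual
convolution blocks at every level, constant filter depth) implemented
directly on numpy: im2col convolutions as matrix products, hand-written
backward passes, Adam updates. Sized for the reduced-resolution CPU regime
this package targets; everything is float32 and fully seeded.

Input is an (N, 3, H, W) stack of three consecutive frames; output is an
(N, 1, H, W) grid of fluid logits. H and W are padded internally to
multiples of 4 (edge replication) and the output is cropped back.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

__all__ = ["ResUNet2D", "Adam", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dL/dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # log(1 + exp(-|z|)) + max(z, 0) - z*y, numerically stable
    loss = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y)
    grad = (sigmoid(logits) - targets.astype(np.float32)) / logits.size
    return float(loss), grad.astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) columns with same-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Conv:
    """k x k same-padding convolution, stored as a (C*k*k, F) matrix."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_in * k * k, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: Tuple[int, int, int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k) if self.k > 1 else x.transpose(0, 2, 3, 1).reshape(-1, c)
        out = cols @ self.W + self.b
        self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.dW[...] = self._cols.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        if self.k == 1:
            dx = dflat @ self.W.T
            return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        # gradient wrt input = convolution of dout with the flipped kernel,
        # in/out channels transposed — expressed as another im2col product
        Wk = self.W.reshape(self.c_in, self.k, self.k, self.c_out)
        Wb = Wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * self.k * self.k, self.c_in)
        cols = _im2col(dout, self.k)
        dx = cols @ Wb
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)

    def params(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class ResBlock:
    """y = relu(x + conv(relu(conv(x)))) at constant channel count."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.c1 = Conv(channels, channels, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv(channels, channels, 3, rng)
        self.r_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        return self.r_out.forward(x + h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.r_out.backward(dout)
        dh = self.c1.backward(self.r1.backward(self.c2.backward(d)))
        return d + dh

    def params(self):
        return self.c1.params() + self.c2.params()


def _pool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_back(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) * 0.25


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_back(d: np.ndarray) -> np.ndarray:
    n, c, h, w = d.shape
    return d.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ResUNet2D:
    """Residual encoder-decoder over 3-frame stacks, constant filter depth."""

    def __init__(self, in_channels: int = 3, filters: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        f = int(filters)
        if f < 1:
            raise ValueError("filter depth must be >= 1")
        self.filters = f
        self.in_channels = in_channels
        self.stem = Conv(in_channels, f, 3, rng)
        self.stem_relu = ReLU()
        self.enc1 = ResBlock(f, rng)
        self.enc2 = ResBlock(f, rng)
        self.bottleneck = ResBlock(f, rng)
        self.dec2 = ResBlock(f, rng)
        self.dec1 = ResBlock(f, rng)
        self.head = Conv(f, 1, 1, rng)
        self._layers = [
            self.stem, self.enc1, self.enc2, self.bottleneck,
            self.dec2, self.dec1, self.head,
        ]

    # -- graph -------------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._pad_hw = (x.shape[2], x.shape[3])
        x = _pad_to_multiple(x, 4)
        x0 = self.stem_relu.forward(self.stem.forward(x))
        x1 = self.enc1.forward(x0)
        x2 = self.enc2.forward(_pool2(x1))
        x3 = self.bottleneck.forward(_pool2(x2))
        u2 = _up2(x3) + x2
        x4 = self.dec2.forward(u2)
        u1 = _up2(x4) + x1
        x5 = self.dec1.forward(u1)
        logits = self.head.forward(x5)
        h, w = self._pad_hw
        return logits[:, :, :h, :w]

    def backward(self, dlogits: np.ndarray) -> None:
        h, w = self._pad_hw
        full_h = -(-h // 4) * 4
        full_w = -(-w // 4) * 4
        d = np.zeros((dlogits.shape[0], 1, full_h, full_w), dtype=np.float32)
        d[:, :, :h, :w] = dlogits
        du1 = self.dec1.backward(self.head.backward(d))
        dx4 = _up2_back(du1)  # upsampled branch of u1 = up(x4) + x1
        dx1 = du1.copy()  # skip branch
        du2 = self.dec2.backward(dx4)
        dx3 = _up2_back(du2)  # upsampled branch of u2 = up(x3) + x2
        dx2 = du2.copy()
        dx2 += _pool2_back(self.bottleneck.backward(dx3))
        dx1 += _pool2_back(self.enc2.backward(dx2))
        dx0 = self.enc1.backward(dx1)
        self.stem.backward(self.stem_relu.backward(dx0))

    def params(self):
        out = self.stem.params() + self.head.params()
        for blk in (self.enc1, self.enc2, self.bottleneck, self.dec2, self.dec1):
            out = out + blk.params()
        return out

    # -- weights I/O ---------------------------------------------------------

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = state[f"p{i}"]


def _pad_to_multiple(x: np.ndarray, m: int) -> np.ndarray:
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
    return x


class Adam:
    """Adam with the standard bias correction; operates on (param, grad) pairs."""

    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
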