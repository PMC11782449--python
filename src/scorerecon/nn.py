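"""Minimal convolutional network toolkit in numpy.

The score network needs only a handful of primitives: 3x3 same-padding
convolutions (stride 1 or 2), per-class learned channel biases, ReLU,
nearest-neighbour 2x upsampling, and Adam.  They are implemented here with
explicit im2col forward passes and hand-written backward passes; a
finite-difference gradient check in the test suite guards every layer.

All arrays are float64 and NCHW: (batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ClassBias", "ReLU", "Upsample2x", "ScoreUNet", "Adam"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H2, W2, C*k*k) patch matrix."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (B, C, H2, W2, k, k)
    b, c, h2, w2, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h2, w2, c * k * k)


class Conv2d:
    """k x k convolution with 'same' zero padding (stride 1) or 2x downsampling."""

    def __init__(self, name, c_in, c_out, k=3, stride=1, rng=None, scale=None):
        self.name = name
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        if scale is None:
            scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        rng = rng or np.random.default_rng(0)
        self.W = rng.standard_normal((c_out, c_in, k, k)) * scale
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        cols = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        wmat = self.W.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, h2, w2 = dout.shape
        d = dout.transpose(0, 2, 3, 1)  # (B, H2, W2, c_out)
        cols = self._cols
        self.dW += (
            d.reshape(-1, self.c_out).T @ cols.reshape(-1, cols.shape[-1])
        ).reshape(self.W.shape)
        self.db += d.sum(axis=(0, 1, 2))
        dcols = (d @ self.W.reshape(self.c_out, -1)).reshape(
            b, h2, w2, self.c_in, self.k, self.k
        )
        _, _, h, w = self._in_shape
        dxp = np.zeros((b, self.c_in, h + 2 * self.pad, w + 2 * self.pad))
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + s * h2 : s, kj : kj + s * w2 : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, self.pad : self.pad + h, self.pad : self.pad + w]


class ClassBias:
    """Learned per-class, per-channel additive embedding: x + e[label]."""

    def __init__(self, name, n_classes, channels):
        self.name = name
        self.E = np.zeros((n_classes, channels))
        self.dE = np.zeros_like(self.E)
        self._labels = None

    def params(self):
        return {f"{self.name}.E": self.E}

    def grads(self):
        return {f"{self.name}.E": self.dE}

    def forward(self, x: np.ndarray, labels: np.ndarray) -> np.ndarray:
        self._labels = labels
        return x + self.E[labels][:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        np.add.at(self.dE, self._labels, dout.sum(axis=(2, 3)))
        return dout


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Upsample2x:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ScoreUNet:
    """Small U-shaped encoder-decoder producing a field the size of its input.

    One 2x downsampling stage with a skip connection across it; class
    conditioning by a learned channel bias after every convolution.  The
    network predicts the *negative noise* ``-z`` on a noise-perturbed input;
    the score at noise scale sigma is its output divided by sigma.
    """

    def __init__(self, channels=16, n_classes=2, seed=0):
        rng = np.random.default_rng(np.random.PCG64(seed))
        c = channels
        self.channels, self.n_classes, self.seed = channels, n_classes, seed
        self.enc1 = Conv2d("enc1", 1, c, rng=rng)
        self.emb1 = ClassBias("emb1", n_classes, c)
        self.act1 = ReLU()
        self.enc2 = Conv2d("enc2", c, 2 * c, stride=2, rng=rng)
        self.emb2 = ClassBias("emb2", n_classes, 2 * c)
        self.act2 = ReLU()
        self.mid = Conv2d("mid", 2 * c, 2 * c, rng=rng)
        self.embm = ClassBias("embm", n_classes, 2 * c)
        self.actm = ReLU()
        self.up = Upsample2x()
        self.dec1 = Conv2d("dec1", 2 * c, c, rng=rng)
        self.embd = ClassBias("embd", n_classes, c)
        self.actd = ReLU()
        self.dec2 = Conv2d("dec2", c, c, rng=rng)
        self.actf = ReLU()
        self.out = Conv2d("out", c, 1, rng=rng, scale=1e-3)
        self._convs = [self.enc1, self.enc2, self.mid, self.dec1, self.dec2, self.out]
        self._embs = [self.emb1, self.emb2, self.embm, self.embd]

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self._convs + self._embs:
            out.update(layer.params())
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self._convs + self._embs:
            out.update(layer.grads())
        return out

    def zero_grads(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        own = self.params()
        if set(own) != set(params):
            raise ValueError("parameter name mismatch")
        for k, v in params.items():
            own[k][...] = v

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """x: (B, H, W) real, H and W even; labels: (B,) int.  Returns (B, H, W)."""
        if x.ndim != 3:
            raise ValueError("expected a batch of 2-D images (B, H, W)")
        if x.shape[1] % 2 or x.shape[2] % 2:
            raise ValueError("image height and width must be even")
        h = x[:, None, :, :]
        h0 = self.act1.forward(self.emb1.forward(self.enc1.forward(h), labels))
        h1 = self.act2.forward(self.emb2.forward(self.enc2.forward(h0), labels))
        hm = self.actm.forward(self.embm.forward(self.mid.forward(h1), labels))
        hu = self.actd.forward(
            self.embd.forward(self.dec1.forward(self.up.forward(hm)), labels)
        )
        hs = hu + h0  # skip connection across the downsampling stage
        hf = self.actf.forward(self.dec2.forward(hs))
        return self.out.forward(hf)[:, 0, :, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.out.backward(dout[:, None, :, :])
        d = self.dec2.backward(self.actf.backward(d))
        d_h0 = d  # skip branch
        d = self.dec1.backward(self.embd.backward(self.actd.backward(d)))
        d = self.up.backward(d)
        d = self.mid.backward(self.embm.backward(self.actm.backward(d)))
        d = self.enc2.backward(self.emb2.backward(self.act2.backward(d)))
        d = d + d_h0
        d = self.enc1.backward(self.emb1.backward(self.act1.backward(d)))
        return d[:, 0, :, :]


class Adam:
    """Adam with bias correction; operates in place on a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
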