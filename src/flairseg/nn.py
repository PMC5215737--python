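"""Minimal CPU neural-network layers for the segmentation autoencoder.

Everything operates on float32 channels-last batches ``(N, H, W, C)``.
Convolutions are 'same' zero-padded and implemented as a sum of nine
shifted matrix products (one per 3x3 tap), which keeps both the forward
and backward passes inside BLAS. Max-pooling uses a 2x2 window and records
the argmax position within each window; max-unpooling places values back
at exactly those positions — the index-passing trick that lets a mirrored
decoder recover sharp boundaries after aggressive downsampling.

Layers expose ``forward``/``backward`` and keep whatever they need for the
backward pass on ``self``; parameters live in ``params()`` as name->array.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2x2", "MaxUnpool2x2", "softmax2", "softmax_xent_grad"]

DT = np.float32


class Conv2D:
    """2-D convolution, kernel ``k`` x ``k``, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out)).astype(DT)
        self.b = np.zeros(c_out, dtype=DT)
        self.k = k
        self._x_pad: np.ndarray | None = None

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = x.shape
        x_pad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (n, h, w, self.b.size)).copy()
        for di in range(k):
            for dj in range(k):
                out += x_pad[:, di : di + h, dj : dj + w, :] @ self.W[di, dj]
        if train:
            self._x_pad = x_pad
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        assert self._x_pad is not None, "forward(train=True) required before backward"
        k = self.k
        x_pad = self._x_pad
        n, h, w, c_out = dout.shape
        c_in = x_pad.shape[-1]
        dW = np.empty_like(self.W)
        dflat = dout.reshape(-1, c_out)
        dx_pad = np.zeros_like(x_pad)
        for di in range(k):
            for dj in range(k):
                patch = x_pad[:, di : di + h, dj : dj + w, :].reshape(-1, c_in)
                dW[di, dj] = patch.T @ dflat
                dx_pad[:, di : di + h, dj : dj + w, :] += dout @ self.W[di, dj].T
        db = dflat.sum(axis=0)
        p = k // 2
        dx = dx_pad[:, p : p + h, p : p + w, :] if p else dx_pad
        return dx, {"W": dW, "b": db}


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2:
    """2x2 max-pooling that records argmax indices for the paired unpool.

    Input spatial dims must be even. ``last_indices`` holds, per output
    element, which of the 4 window positions (row-major) held the max.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        n, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0, "pooling needs even spatial dims"
        win = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._in_shape = x.shape
            self._idx = idx
        return out, idx

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return unpool_scatter(dout, self._idx, self._in_shape)


def unpool_scatter(values: np.ndarray, idx: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Place ``values`` at the recorded 2x2 window positions, zero elsewhere."""
    n, hh, wh, c = values.shape
    win = np.zeros((n, hh, wh, c, 4), dtype=values.dtype)
    np.put_along_axis(win, idx[..., None], values[..., None], axis=-1)
    out = (
        win.reshape(n, hh, wh, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(out_shape)
    )
    return out


class MaxUnpool2x2:
    """Nonlinear 2x upsampling driven by encoder pooling indices."""

    def forward(
        self, x: np.ndarray, idx: np.ndarray, out_shape: tuple, train: bool = False
    ) -> np.ndarray:
        if train:
            self._idx = idx
        return unpool_scatter(x, idx, out_shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        win = (
            dout.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]


def softmax2(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over the last axis (the 2 class channels)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent_grad(
    prob: np.ndarray, labels: np.ndarray, weight: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted mean per-pixel 2-class cross-entropy and its logit gradient.

    ``labels`` is {0,1} per pixel (class-1 indicator); ``weight`` masks out
    padded pixels. Returns (loss, d_logits).
    """
    wsum = weight.sum()
    p1 = np.clip(prob[..., 1], 1e-12, 1.0)
    p0 = np.clip(prob[..., 0], 1e-12, 1.0)
    ll = labels * np.log(p1) + (1 - labels) * np.log(p0)
    loss = float(-(ll * weight).sum() / wsum)
    onehot = np.stack([1 - labels, labels], axis=-1)
    dlogits = (prob - onehot) * (weight[..., None] / wsum)
    return loss, dlogits.astype(prob.dtype)
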