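"""A convolutional LSTM sequence classifier in plain NumPy.

The network classifies sEMG windows shaped as (n, T, 1, W, C) tensors:
T subsequences, a spatial height of one, W columns and C electrode
channels.  Layer sequence:

    ConvLSTM(F filters, kernel 1 x k, valid padding)
      -> dropout p1 -> flatten
      -> dense d1 (ReLU) -> dense d2 (ReLU) -> dropout p2
      -> dense n_classes (softmax)

The convolutional LSTM replaces the inner products of a standard LSTM
with convolutions over the width axis, in both the input-to-state and
state-to-state transforms, so gates retain the electrode-array layout.
Because the height is one, the 1 x k kernel is a 1-D convolution along
the 20-column axis.

Training uses class-weighted categorical cross-entropy, Adam with
default parameters, inverted dropout and backpropagation through time.
Gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["ConvLSTMNet", "Adam"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col_valid(x: np.ndarray, k: int) -> np.ndarray:
    """(B, W, C) -> (B, W-k+1, k*C); feature j*C+c is x[p+j, c]."""
    B, W, C = x.shape
    wout = W - k + 1
    cols = np.empty((B, wout, k, C), dtype=x.dtype)
    for j in range(k):
        cols[:, :, j, :] = x[:, j : j + wout, :]
    return cols.reshape(B, wout, k * C)


def _im2col_same(x: np.ndarray, k: int) -> np.ndarray:
    """(B, W, C) -> (B, W, k*C) with zero padding (odd k)."""
    pad = (k - 1) // 2
    B, W, C = x.shape
    xp = np.zeros((B, W + 2 * pad, C), dtype=x.dtype)
    xp[:, pad : pad + W, :] = x
    return _im2col_valid(xp, k)


def _col2im_same(dcols: np.ndarray, k: int, width: int) -> np.ndarray:
    """Adjoint of :func:`_im2col_same`."""
    pad = (k - 1) // 2
    B, W, kC = dcols.shape
    C = kC // k
    d = dcols.reshape(B, W, k, C)
    out = np.zeros((B, width + 2 * pad, C), dtype=dcols.dtype)
    for j in range(k):
        out[:, j : j + W, :] += d[:, :, j, :]
    return out[:, pad : pad + width, :]


class ConvLSTMNet:
    """ConvLSTM + dense head; parameters in a flat dict for the optimizer."""

    def __init__(
        self,
        n_filters: int = 128,
        kernel_w: int = 3,
        dense_units: tuple[int, int] = (200, 50),
        n_classes: int = 11,
        n_subseq: int = 10,
        width: int = 20,
        channels: int = 12,
        dropout1: float = 0.5,
        dropout2: float = 0.2,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.F = n_filters
        self.k = kernel_w
        self.T = n_subseq
        self.W = width
        self.C = channels
        self.wout = width - kernel_w + 1
        if self.wout < 1:
            raise ValueError(f"kernel width {kernel_w} exceeds input width {width}")
        self.n_classes = n_classes
        self.dense_units = tuple(dense_units)
        self.dropout1 = dropout1
        self.dropout2 = dropout2
        self.dtype = dtype
        self.seed = seed
        self.params = self._init_params(np.random.default_rng(seed))

    def _glorot(self, rng, fan_in, fan_out, shape):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(self.dtype)

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        F, k, C = self.F, self.k, self.C
        d1, d2 = self.dense_units
        flat = self.wout * F
        b = np.zeros(4 * F, dtype=self.dtype)
        b[F : 2 * F] = 1.0  # forget-gate bias
        return {
            "Wx": self._glorot(rng, k * C, F, (k * C, 4 * F)),
            "Wh": self._glorot(rng, k * F, F, (k * F, 4 * F)),
            "b": b,
            "W1": self._glorot(rng, flat, d1, (flat, d1)),
            "b1": np.zeros(d1, dtype=self.dtype),
            "W2": self._glorot(rng, d1, d2, (d1, d2)),
            "b2": np.zeros(d2, dtype=self.dtype),
            "W3": self._glorot(rng, d2, self.n_classes, (d2, self.n_classes)),
            "b3": np.zeros(self.n_classes, dtype=self.dtype),
        }

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Class probabilities for a batch; returns (probs, cache)."""
        p = self.params
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 5:  # (B, T, 1, W, C)
            X = X.reshape(X.shape[0], X.shape[1], X.shape[3], X.shape[4])
        B = X.shape[0]
        F = self.F
        h = np.zeros((B, self.wout, F), dtype=self.dtype)
        c = np.zeros_like(h)
        steps = []
        for t in range(self.T):
            cols = _im2col_valid(X[:, t], self.k)
            hcols = _im2col_same(h, self.k)
            z = cols @ p["Wx"] + hcols @ p["Wh"] + p["b"]
            i = _sigmoid(z[..., :F])
            f = _sigmoid(z[..., F : 2 * F])
            g = np.tanh(z[..., 2 * F : 3 * F])
            o = _sigmoid(z[..., 3 * F :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            steps.append((cols, hcols, i, f, g, o, c_prev, tc))

        if train and self.dropout1 > 0:
            mask1 = (rng.uniform(size=h.shape) >= self.dropout1).astype(self.dtype) / (
                1.0 - self.dropout1
            )
        else:
            mask1 = None
        hd = h * mask1 if mask1 is not None else h
        flat = hd.reshape(B, -1)
        a1 = np.maximum(flat @ p["W1"] + p["b1"], 0.0)
        a2 = np.maximum(a1 @ p["W2"] + p["b2"], 0.0)
        if train and self.dropout2 > 0:
            mask2 = (rng.uniform(size=a2.shape) >= self.dropout2).astype(self.dtype) / (
                1.0 - self.dropout2
            )
        else:
            mask2 = None
        a2d = a2 * mask2 if mask2 is not None else a2
        logits = a2d @ p["W3"] + p["b3"]
        logits64 = logits.astype(np.float64)
        logits64 -= logits64.max(axis=1, keepdims=True)
        e = np.exp(logits64)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (steps, mask1, h, flat, a1, a2, mask2, a2d)
        return probs, cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Inference-mode probabilities, chunked to bound memory."""
        outs = []
        for s in range(0, len(X), batch_size):
            probs, _ = self.forward(X[s : s + batch_size], train=False)
            outs.append(probs)
        return np.concatenate(outs) if outs else np.empty((0, self.n_classes))

    # ------------------------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients for upstream dL/dlogits."""
        p = self.params
        steps, mask1, h, flat, a1, a2, mask2, a2d = cache
        B = dlogits.shape[0]
        F = self.F
        dlogits = dlogits.astype(self.dtype)
        grads = {}
        grads["W3"] = a2d.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        da2d = dlogits @ p["W3"].T
        da2 = da2d * mask2 if mask2 is not None else da2d
        da2 = da2 * (a2 > 0)
        grads["W2"] = a1.T @ da2
        grads["b2"] = da2.sum(axis=0)
        da1 = da2 @ p["W2"].T
        da1 = da1 * (a1 > 0)
        grads["W1"] = flat.T @ da1
        grads["b1"] = da1.sum(axis=0)
        dflat = da1 @ p["W1"].T
        dh = dflat.reshape(h.shape)
        if mask1 is not None:
            dh = dh * mask1

        dWx = np.zeros_like(p["Wx"])
        dWh = np.zeros_like(p["Wh"])
        db = np.zeros_like(p["b"])
        dc_next = np.zeros_like(dh)
        for t in range(self.T - 1, -1, -1):
            cols, hcols, i, f, g, o, c_prev, tc = steps[t]
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=-1,
            )
            dz2 = dz.reshape(-1, 4 * F)
            dWx += cols.reshape(dz2.shape[0], -1).T @ dz2
            dWh += hcols.reshape(dz2.shape[0], -1).T @ dz2
            db += dz2.sum(axis=0)
            dhcols = dz @ p["Wh"].T
            dh = _col2im_same(dhcols, self.k, self.wout)
        grads["Wx"] = dWx
        grads["Wh"] = dWh
        grads["b"] = db
        return grads

    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        sample_weights: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        train: bool = True,
    ):
        """Weighted cross-entropy loss, gradients and batch probabilities."""
        probs, cache = self.forward(X, train=train, rng=rng)
        B = len(y)
        w = np.ones(B) if sample_weights is None else np.asarray(sample_weights, dtype=np.float64)
        py = np.clip(probs[np.arange(B), y], 1e-12, None)
        loss = float(np.mean(w * -np.log(py)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (w / B)[:, None]
        grads = self.backward(cache, dlogits)
        return loss, grads, probs

    # ------------------------------------------------------------------
    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=self.dtype).copy()


class Adam:
    """Adam optimizer with the customary default parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        for k, p in params.items():
            g = grads[k].astype(p.dtype)
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)).astype(p.dtype)
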