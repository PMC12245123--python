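"""Minimal numpy neural-network layers with explicit backpropagation.

Supplies exactly what the spectral regression models need: 1D/2D convolution
(im2col), batch normalization, ReLU, residual blocks, pooling, fully
connected layers, the batch-correlation feature-update layer, an MAE loss,
and the Nadam optimizer.  Every layer caches its forward activations and
implements an exact backward pass; correctness is pinned by central
finite-difference tests.

All layers run in the dtype of their parameters (float32 by default;
float64 for gradient checking).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    training: bool = True

    def children(self):
        return []

    def modules(self):
        yield self
        for c in self.children():
            yield from c.modules()

    def params(self) -> list[Parameter]:
        out = []
        for m in self.modules():
            out.extend(getattr(m, "_params", []))
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / in_dim)
        self.w = Parameter(rng.normal(0.0, scale, (out_dim, in_dim)).astype(dtype))
        self.b = Parameter(np.zeros(out_dim, dtype=dtype))
        self._params = [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv2d(Module):
    """3x3/5x5-style convolution via im2col; stride and zero padding."""

    def __init__(self, in_c, out_c, k, rng, stride=1, pad=None, dtype=np.float32):
        self.in_c, self.out_c, self.k = in_c, out_c, k
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (in_c * k * k))
        self.w = Parameter(rng.normal(0.0, scale, (out_c, in_c * k * k)).astype(dtype))
        self.b = Parameter(np.zeros(out_c, dtype=dtype))
        self._params = [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        y = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(n, ho, wo, self.out_c).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.out_c)
        self.w.grad += dyf.T @ cols
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.w.value).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Conv1d(Module):
    def __init__(self, in_c, out_c, k, rng, stride=1, pad=None, dtype=np.float32):
        self.in_c, self.out_c, self.k = in_c, out_c, k
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (in_c * k))
        self.w = Parameter(rng.normal(0.0, scale, (out_c, in_c * k)).astype(dtype))
        self.b = Parameter(np.zeros(out_c, dtype=dtype))
        self._params = [self.w, self.b]

    def forward(self, x):
        n, c, l = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        lo = (l + 2 * p - k) // s + 1
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * lo, c * k)
        y = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, lo)
        return y.reshape(n, lo, self.out_c).transpose(0, 2, 1)

    def backward(self, dy):
        cols, xshape, lo = self._cache
        n, c, l = xshape
        k, s, p = self.k, self.stride, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(-1, self.out_c)
        self.w.grad += dyf.T @ cols
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.w.value).reshape(n, lo, c, k)
        dxp = np.zeros((n, c, l + 2 * p), dtype=dy.dtype)
        for i in range(k):
            dxp[:, :, i : i + s * lo : s] += dcols[:, :, :, i].transpose(0, 2, 1)
        return dxp[:, :, p : p + l] if p else dxp


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, channels: int, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self._params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x):
        sh = self._shape(x)
        axes = tuple(i for i in range(x.ndim) if i != 1)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            mom = self.momentum
            self.running_mean = ((1 - mom) * self.running_mean + mom * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - mom) * self.running_var + mom * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv_std.reshape(sh)
        self._cache = (xhat, inv_std, axes, self.training)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, dy):
        xhat, inv_std, axes, trained = self._cache
        sh = self._shape(dy)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(sh)
        if not trained:
            return dy * g * inv_std.reshape(sh)
        m = dy.size / dy.shape[1]
        dxhat = dy * g
        return (
            inv_std.reshape(sh)
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes).reshape(sh)
                - xhat * (dxhat * xhat).sum(axis=axes).reshape(sh)
            )
        )


class MaxPool2d(Module):
    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape, ho, wo)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        idx, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for f in range(k * k):
            i, j = divmod(f, k)
            mask = idx == f
            dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dy * mask
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class AvgPool2d(Module):
    """Non-overlapping k x k mean pooling (input size must divide by k)."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool size {k}")
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        k = self.k
        dx = np.broadcast_to(
            dy[:, :, :, None, :, None], (n, c, h // k, k, w // k, k)
        ) / (k * k)
        return dx.reshape(n, c, h, w).astype(dy.dtype)


class GlobalAvgPool(Module):
    """(N, C, ...) -> (N, C) mean over spatial axes."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        sh = self._shape
        spatial = int(np.prod(sh[2:]))
        return np.broadcast_to(
            dy.reshape(sh[:2] + (1,) * (len(sh) - 2)), sh
        ).astype(dy.dtype) / spatial


class ResidualBlock2d(Module):
    def __init__(self, in_c, out_c, rng, stride=1, dtype=np.float32):
        self.main = Sequential(
            Conv2d(in_c, out_c, 3, rng, stride=stride, dtype=dtype),
            BatchNorm(out_c, dtype=dtype),
            ReLU(),
            Conv2d(out_c, out_c, 3, rng, dtype=dtype),
            BatchNorm(out_c, dtype=dtype),
        )
        self.skip = None
        if in_c != out_c or stride != 1:
            self.skip = Sequential(
                Conv2d(in_c, out_c, 1, rng, stride=stride, pad=0, dtype=dtype),
                BatchNorm(out_c, dtype=dtype),
            )

    def children(self):
        return [self.main] + ([self.skip] if self.skip else [])

    def forward(self, x):
        h = self.main.forward(x)
        sk = self.skip.forward(x) if self.skip else x
        y = h + sk
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy):
        dsum = dy * self._mask
        dx = self.main.backward(dsum)
        dx = dx + (self.skip.backward(dsum) if self.skip else dsum)
        return dx


class ResidualBlock1d(Module):
    def __init__(self, in_c, out_c, rng, stride=1, dtype=np.float32):
        self.main = Sequential(
            Conv1d(in_c, out_c, 3, rng, stride=stride, dtype=dtype),
            BatchNorm(out_c, dtype=dtype),
            ReLU(),
            Conv1d(out_c, out_c, 3, rng, dtype=dtype),
            BatchNorm(out_c, dtype=dtype),
        )
        self.skip = None
        if in_c != out_c or stride != 1:
            self.skip = Sequential(
                Conv1d(in_c, out_c, 1, rng, stride=stride, pad=0, dtype=dtype),
                BatchNorm(out_c, dtype=dtype),
            )

    def children(self):
        return [self.main] + ([self.skip] if self.skip else [])

    forward = ResidualBlock2d.forward
    backward = ResidualBlock2d.backward


# ---------------------------------------------------------------------------
# Batch correlation
# ---------------------------------------------------------------------------

def _batch_correlation_forward(F, mode: str, temperature: float):
    norms = np.linalg.norm(F, axis=1)
    if np.any(norms == 0):
        raise ValueError("batch correlation undefined for a zero-norm feature row")
    U = F / norms[:, None]
    S = U @ U.T
    if mode == "softmax":
        logits = S / temperature
        logits = logits - logits.max(axis=1, keepdims=True)
        E = np.exp(logits)
        A = E / E.sum(axis=1, keepdims=True)
    elif mode == "sum_pos":
        P = np.maximum(S, 0.0)
        A = P / P.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown batch-correlation mode {mode!r}")
    return A @ F, (F, U, norms, S, A)


def batch_correlation(F, mode: str = "softmax", temperature: float = 1.0) -> np.ndarray:
    """Update each feature row as a convex combination of all rows in the
    batch, weighted by (normalized) cosine similarity.

    With ``mode='softmax'`` the weights for row i are
    ``a_k = softmax_k(sim(F_i, F_k) / temperature)``; with ``mode='sum_pos'``
    they are the positive-part similarities normalized to sum to one.  The
    output has the input's shape, each row lying in the convex hull of the
    input rows; a single-row batch (or identical rows) is returned unchanged.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ValueError("expected a (N, D) feature batch")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite feature value")
    out, _ = _batch_correlation_forward(F, mode, temperature)
    return out


class BatchCorrelation(Module):
    """Batch-correlation layer.

    In training (and in ``cohort_inference`` mode) features are mixed across
    the batch; in per-sample inference the layer is the identity so that a
    prediction never depends on unrelated co-batched spectra.
    """

    def __init__(self, mode="softmax", temperature=1.0, cohort_inference=False):
        self.mode = mode
        self.temperature = temperature
        self.cohort_inference = cohort_inference

    def forward(self, F):
        if not self.training and not self.cohort_inference:
            self._cache = None
            return F
        out, cache = _batch_correlation_forward(F, self.mode, self.temperature)
        self._cache = cache
        return out

    def backward(self, dY):
        if self._cache is None:
            return dY
        F, U, norms, S, A = self._cache
        dF = A.T @ dY
        dA = dY @ F.T
        if self.mode == "softmax":
            dS = A * (dA - (dA * A).sum(axis=1, keepdims=True)) / self.temperature
        else:
            P = np.maximum(S, 0.0)
            srow = P.sum(axis=1, keepdims=True)
            dP = (dA - (dA * A).sum(axis=1, keepdims=True)) / srow
            dS = dP * (S > 0)
        dU = dS @ U + dS.T @ U
        dF += (dU - (dU * U).sum(axis=1, keepdims=True) * U) / norms[:, None]
        return dF


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error over all entries; returns (loss, dloss/dpred)."""
    diff = pred - target
    grad = np.sign(diff).astype(pred.dtype) / diff.size
    return float(np.abs(diff).mean()), grad


class Nadam:
    """Nesterov-accelerated Adam (Dozat 2016), the optimizer of the training
    protocol; initial learning rate 1e-3."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        t = self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p.value -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                p.value.dtype
            )
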