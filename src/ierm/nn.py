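"""Minimal neural-network layers with manual backpropagation.

Implements exactly the pieces the emotion classifier needs — 2-D same-padding
convolution, batch normalization, efficient channel attention, dropout, leaky
ReLU, 2x2 max pooling, LSTM, linear, sigmoid/MSE — each as a layer object with
``forward``/``backward`` and an Adam optimizer.  All arithmetic is float64
numpy; gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ECALayer",
    "Dropout",
    "LeakyReLU",
    "MaxPool2d",
    "Linear",
    "LSTM",
    "Adam",
    "sigmoid",
    "mse_loss",
]


class Param:
    """A learnable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element; returns (loss, dL/dpred)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Stride-1 2-D convolution with symmetric zero padding (same output size)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for same-padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Param(rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel, kernel)), "conv.w")
        self.bias = Param(rng.uniform(-bound, bound, size=out_ch), "conv.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) windows -> (N, H*W, C*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * self.k * self.k)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        p = self.k // 2
        g = grad.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)  # (N, H*W, O)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        self.weight.grad += np.einsum("npo,npk->ok", g, cols).reshape(self.weight.value.shape)
        self.bias.grad += g.sum(axis=(0, 1))
        dcols = (g @ wmat).reshape(n, h, w, c, self.k, self.k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            # unbiased running variance, as is conventional
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gsc = grad * self.gamma.value[None, :, None, None]
        if not train:
            return gsc * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        sum_g = gsc.sum(axis=(0, 2, 3))
        sum_gx = (gsc * xhat).sum(axis=(0, 2, 3))
        return (
            inv[None, :, None, None]
            / m
            * (m * gsc - sum_g[None, :, None, None] - xhat * sum_gx[None, :, None, None])
        )


class ECALayer(Layer):
    """Efficient channel attention: GAP over space, 1-D conv across channels,
    sigmoid gate, broadcast multiply.  Kernel size is supplied by the caller
    (adaptive in the number of channels)."""

    def __init__(self, kernel: int, rng: np.random.Generator) -> None:
        if kernel % 2 != 1:
            raise ValueError("ECA kernel must be odd")
        self.k = kernel
        bound = 1.0 / np.sqrt(kernel)
        self.weight = Param(rng.uniform(-bound, bound, size=kernel), "eca.w")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight]

    def channel_weights(self, x: np.ndarray) -> np.ndarray:
        g = x.mean(axis=(2, 3))
        p = self.k // 2
        gp = np.pad(g, ((0, 0), (p, p)))
        z = np.zeros_like(g)
        for j in range(self.k):
            z += self.weight.value[j] * gp[:, j : j + g.shape[1]]
        return sigmoid(z)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        g = x.mean(axis=(2, 3))  # (N, C)
        p = self.k // 2
        gp = np.pad(g, ((0, 0), (p, p)))
        z = np.zeros_like(g)
        for j in range(self.k):
            z += self.weight.value[j] * gp[:, j : j + c]
        a = sigmoid(z)
        self._cache = (x, gp, a)
        return x * a[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, gp, a = self._cache
        n, c, h, w = x.shape
        p = self.k // 2
        dx = grad * a[:, :, None, None]
        da = (grad * x).sum(axis=(2, 3))
        dz = da * a * (1.0 - a)
        dgp = np.zeros_like(gp)
        for j in range(self.k):
            self.weight.grad[j] += float(np.sum(dz * gp[:, j : j + c]))
            dgp[:, j : j + c] += dz * self.weight.value[j]
        dg = dgp[:, p : p + c]
        dx += dg[:, :, None, None] / (h * w)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class MaxPool2d(Layer):
    """Non-overlapping pooling with floor semantics (trailing rows/cols dropped)."""

    def __init__(self, size: int = 2) -> None:
        self.s = size
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.s
        h2, w2 = h // s, w // s
        xc = x[:, :, : h2 * s, : w2 * s].reshape(n, c, h2, s, w2, s)
        xc = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, s * s)
        idx = xc.argmax(axis=-1)
        out = np.take_along_axis(xc, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        s = self.s
        h2, w2 = h // s, w // s
        dflat = np.zeros((n, c, h2, w2, s * s))
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : h2 * s, : w2 * s] = (
            dflat.reshape(n, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * s, w2 * s)
        )
        return dx


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Param(rng.uniform(-bound, bound, size=(d_out, d_in)), "linear.w")
        self.bias = Param(rng.uniform(-bound, bound, size=d_out), "linear.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class LSTM(Layer):
    """Single-layer LSTM over (N, T, D) inputs, returning all hidden states.

    Gate pre-activations are computed from the concatenation [h_{t-1}, x_t]
    with one stacked weight matrix; rows are ordered (input, forget,
    candidate, output).  The forget-gate bias starts at 1.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        self.d_in, self.h = d_in, hidden
        bound = 1.0 / np.sqrt(hidden)
        self.weight = Param(rng.uniform(-bound, bound, size=(4 * hidden, hidden + d_in)), "lstm.w")
        b = rng.uniform(-bound, bound, size=4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.bias = Param(b, "lstm.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, d = x.shape
        hdim = self.h
        h = np.zeros((n, hdim))
        c = np.zeros((n, hdim))
        hs = np.zeros((n, t, hdim))
        steps = []
        for step in range(t):
            xt = x[:, step, :]
            z = np.concatenate([h, xt], axis=1)
            pre = z @ self.weight.value.T + self.bias.value
            i = sigmoid(pre[:, :hdim])
            f = sigmoid(pre[:, hdim : 2 * hdim])
            g = np.tanh(pre[:, 2 * hdim : 3 * hdim])
            o = sigmoid(pre[:, 3 * hdim :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, step, :] = h
            steps.append((z, i, f, g, o, c_prev, tc))
        self._cache = (steps, x.shape)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        steps, (n, t, d) = self._cache
        hdim = self.h
        dx = np.zeros((n, t, d))
        dh_next = np.zeros((n, hdim))
        dc_next = np.zeros((n, hdim))
        for step in range(t - 1, -1, -1):
            z, i, f, g, o, c_prev, tc = steps[step]
            dh = dhs[:, step, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dpre = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.weight.grad += dpre.T @ z
            self.bias.grad += dpre.sum(axis=0)
            dz = dpre @ self.weight.value
            dh_next = dz[:, :hdim]
            dx[:, step, :] = dz[:, hdim:]
        return dx


class Adam:
    """Adam with the usual bias correction; default betas (0.9, 0.999)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
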