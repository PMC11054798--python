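"""Minimal CPU neural-network layer library with explicit backpropagation.

Implements exactly the primitives the gait-phase estimators need: dilated
1-D convolutions along the time axis of a feature tensor, a
height-collapsing convolution, batch normalization, leaky ReLU, dropout,
dense layers, and an Adam optimizer. Feature maps are 2-D (channel-height x
time-width); time convolutions slide only along width, so the channel row
of every feature keeps its meaning through the depth of the network.

Tensors are laid out channels-last, (batch, height, width, maps), so each
convolution tap is a single contiguous matrix product.

All randomness flows through an explicit ``numpy.random.Generator``, so
initialization and dropout are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

#: Compute dtype for parameters and activations; single precision keeps the
#: small networks memory-bandwidth friendly on CPU.
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Param",
    "Layer",
    "TimeConv",
    "HeightCollapseConv",
    "BatchNorm",
    "LeakyReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # fan-in scaled uniform init with the leaky-ReLU gain
    gain = np.sqrt(2.0 / (1.0 + 0.01**2))
    limit = gain * np.sqrt(3.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class TimeConv(Layer):
    """Convolution along the time (width) axis with optional dilation.

    Input (B, H, W, Kin) -> output (B, H, W, Kout). Width is preserved by
    symmetric zero padding (``padding="symmetric"``) or by left-only
    padding for a strictly causal variant (``padding="causal"``).
    """

    def __init__(self, k_in: int, k_out: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 padding: str = "symmetric"):
        if padding not in ("symmetric", "causal"):
            raise ValueError("padding must be 'symmetric' or 'causal'")
        if kernel % 2 == 0 and padding == "symmetric":
            raise ValueError("symmetric padding needs an odd kernel size")
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.dilation = dilation
        self.padding = padding
        self.k_in = k_in
        # taps stacked row-wise: (kernel * Kin, Kout)
        self.w = Param(_he_uniform(rng, (kernel * k_in, k_out), k_in * kernel))
        self.b = Param(np.zeros(k_out, dtype=DTYPE))
        self._xcol: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def _pads(self) -> tuple[int, int]:
        span = self.dilation * (self.kernel - 1)
        if self.padding == "symmetric":
            return span // 2, span - span // 2
        return span, 0

    def forward(self, x, train):
        b, h, width, k = x.shape
        if width < 1:
            raise ValueError("time width must be >= 1")
        pl, pr = self._pads()
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        # im2col: (B, H, W, kernel*Kin) gathered tap slices, one GEMM total
        cols = [xp[:, :, t * self.dilation:t * self.dilation + width, :]
                for t in range(self.kernel)]
        xcol = np.concatenate(cols, axis=3).reshape(b * h * width, -1)
        self._xcol = xcol
        self._in_shape = (b, h, width, k, pl, pr)
        out = xcol @ self.w.value + self.b.value
        return out.reshape(b, h, width, -1)

    def backward(self, grad):
        b, h, width, k, pl, pr = self._in_shape
        g2 = np.ascontiguousarray(grad).reshape(b * h * width, -1)
        self.w.grad += self._xcol.T @ g2
        self.b.grad += g2.sum(axis=0)
        gcol = (g2 @ self.w.value.T).reshape(b, h, width, self.kernel, k)
        gxp = np.zeros((b, h, width + pl + pr, k), dtype=grad.dtype)
        for t in range(self.kernel):
            o = t * self.dilation
            gxp[:, :, o:o + width, :] += gcol[:, :, :, t, :]
        return gxp[:, :, pl:pl + width, :]


class HeightCollapseConv(Layer):
    """Unpadded convolution spanning the full channel height.

    Input (B, H, W, Kin) -> (B, 1, W, Kout): collapses the channel rows
    into a single-row time signal, as the estimator's final 1 x H layer.
    """

    def __init__(self, k_in: int, k_out: int, height: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.height = height
        self.w = Param(_he_uniform(rng, (height, k_in, k_out), k_in * height))
        self.b = Param(np.zeros(k_out, dtype=DTYPE))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if x.shape[1] != self.height:
            raise ValueError(
                f"expected feature-map height {self.height}, got {x.shape[1]}")
        self._x = x
        # (b,h,w,k) x (h,k,o) -> (b,w,o)
        out = np.tensordot(x, self.w.value, axes=([1, 3], [0, 1]))
        return out[:, None, :, :] + self.b.value

    def backward(self, grad):
        g = grad[:, 0, :, :]  # (b,w,o)
        self.w.grad += np.tensordot(self._x, g, axes=([0, 2], [0, 1]))
        self.b.grad += g.sum(axis=(0, 1))
        # (b,w,o) x (h,k,o) -> (b,w,h,k) -> (b,h,w,k)
        gx = np.tensordot(g, self.w.value, axes=([2], [2]))
        return np.transpose(gx, (0, 2, 1, 3))


class BatchNorm(Layer):
    """Per-map batch normalization over (batch, height, width).

    ``decay`` is the running-statistics update rate: running <- (1-decay) *
    running + decay * batch. Training uses batch statistics, evaluation the
    running ones.
    """

    def __init__(self, k: int, decay: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(k, dtype=DTYPE))
        self.beta = Param(np.zeros(k, dtype=DTYPE))
        self.decay = decay
        self.eps = eps
        self.running_mean = np.zeros(k, dtype=DTYPE)
        self.running_var = np.ones(k, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (1 - self.decay) * self.running_mean + self.decay * mean
            self.running_var = (1 - self.decay) * self.running_var + self.decay * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, std, train = self._cache
        sum_g = grad.sum(axis=(0, 1, 2))
        sum_gx = (grad * xhat).sum(axis=(0, 1, 2))
        self.gamma.grad += sum_gx
        self.beta.grad += sum_g
        if not train:
            # running statistics are constants: plain affine backward
            return grad * (self.gamma.value / std)
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        return (self.gamma.value / std) * (grad - sum_g / m - xhat * sum_gx / m)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random(x.shape, dtype=np.float32) < keep
        self._mask = mask.astype(x.dtype) / np.asarray(keep, dtype=x.dtype)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Param(_he_uniform(rng, (d_in, d_out), d_in))
        self.b = Param(np.zeros(d_out, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[:] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[:] = b1 * m + (1 - b1) * p.grad
            v[:] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
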