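"""Minimal CPU neural-network layers (numpy, explicit backprop).

Activations are stored channel-first as (C, N, H, W): a convolution kernel
tap is then a single fat GEMM ``(C_out, C_in) @ (C_in, N*H*W)`` on a
contiguous reshape view, which keeps BLAS efficient even for narrow layers
where per-sample batched GEMMs would be memory-bound. The 3x3 convolution
uses the shift decomposition — one pointwise GEMM per tap accumulated into
shifted output views — avoiding the 9x im2col patch buffer entirely.

Each layer caches what its backward pass needs during forward(train=True);
backward(grad) returns the gradient with respect to the layer input and
accumulates parameter gradients in-place. Every backward pass is covered by
finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "weight_decay")

    def __init__(self, value: np.ndarray, weight_decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.weight_decay = weight_decay


class Layer:
    """Base layer operating on (C, N, H, W) activations."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (pad 1) or 1x1 convolution, stride 1."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.ksize = cin, cout, ksize
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(cout, dtype=dtype), weight_decay=False)
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        C, N, H, W = x.shape
        if train:
            self._cache = x
        if self.ksize == 1:
            out = self.weight.value @ x.reshape(C, N * H * W)
            out = out.reshape(self.cout, N, H, W)
            out += self.bias.value[:, None, None, None]
            return out
        w3 = self.weight.value.reshape(self.cout, C, 3, 3)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        xf = xp.reshape(C, N * (H + 2) * (W + 2))
        out = np.zeros((self.cout, N, H, W), dtype=x.dtype)
        for di in range(3):
            for dj in range(3):
                yk = (w3[:, :, di, dj] @ xf).reshape(self.cout, N, H + 2, W + 2)
                out += yk[:, :, di : di + H, dj : dj + W]
        out += self.bias.value[:, None, None, None]
        return out

    def backward(self, grad):
        x = self._cache
        C, N, H, W = x.shape
        g = grad.reshape(self.cout, N * H * W)
        self.bias.grad += g.sum(axis=1)
        if self.ksize == 1:
            xf = x.reshape(C, N * H * W)
            self.weight.grad += g @ xf.T
            return (self.weight.value.T @ g).reshape(C, N, H, W)
        w3 = self.weight.value.reshape(self.cout, C, 3, 3)
        dw3 = self.weight.grad.reshape(self.cout, C, 3, 3)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xk = np.ascontiguousarray(
                    xp[:, :, di : di + H, dj : dj + W]
                ).reshape(C, N * H * W)
                dw3[:, :, di, dj] += g @ xk.T
                gk = (w3[:, :, di, dj].T @ g).reshape(C, N, H, W)
                dxp[:, :, di : di + H, dj : dj + W] += gk
        return np.ascontiguousarray(dxp[:, :, 1 : 1 + H, 1 : 1 + W])


class BatchNorm2d(Layer):
    """Per-channel batch normalization over the (N, H, W) axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype), weight_decay=False)
        self.beta = Param(np.zeros(c, dtype=dtype), weight_decay=False)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None, None]) * inv_std[:, None, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value[:, None, None, None] * xhat + \
            self.beta.value[:, None, None, None]

    def backward(self, grad):
        xhat, inv_std = self._cache
        M = grad.shape[1] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += grad.sum(axis=(1, 2, 3))
        g = grad * self.gamma.value[:, None, None, None]
        gsum = g.sum(axis=(1, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(1, 2, 3), keepdims=True)
        dx = (inv_std[:, None, None, None] / M) * (M * g - gsum - xhat * gxsum)
        return dx.astype(grad.dtype)


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when p == 0 or in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0 <= p < 1):
            raise ValueError("dropout p must lie in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape, dtype=np.float32) >= self.p)
        self._mask = keep.astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool2(Layer):
    def forward(self, x, train=False):
        C, N, H, W = x.shape
        xr = x.reshape(C, N, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(C, N, H // 2, W // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return out

    def backward(self, grad):
        (C, N, H, W), idx = self._cache
        dxr = np.zeros((C, N, H // 2, W // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
        dxr = dxr.reshape(C, N, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(C, N, H, W)


class Upsample2(Layer):
    """2x spatial upsampling, nearest-neighbor or separable bilinear."""

    def __init__(self, mode: str = "nearest"):
        if mode not in ("nearest", "bilinear"):
            raise ValueError("mode must be 'nearest' or 'bilinear'")
        self.mode = mode

    @staticmethod
    def _axis_up(x: np.ndarray, axis: int) -> np.ndarray:
        # half-pixel-centered 2x bilinear along one axis: weights (0.75, 0.25),
        # edge samples clamped
        x = np.moveaxis(x, axis, 0)
        lo = np.concatenate([x[:1], x[:-1]], axis=0)   # x[i-1], clamped
        hi = np.concatenate([x[1:], x[-1:]], axis=0)   # x[i+1], clamped
        even = 0.75 * x + 0.25 * lo
        odd = 0.75 * x + 0.25 * hi
        out = np.empty((2 * x.shape[0], *x.shape[1:]), dtype=x.dtype)
        out[0::2] = even
        out[1::2] = odd
        return np.moveaxis(out, 0, axis)

    @staticmethod
    def _axis_down(g: np.ndarray, axis: int) -> np.ndarray:
        # exact adjoint of _axis_up
        g = np.moveaxis(g, axis, 0)
        even, odd = g[0::2], g[1::2]
        dx = 0.75 * (even + odd)
        dx[:-1] += 0.25 * even[1:]
        dx[1:] += 0.25 * odd[:-1]
        dx[0] += 0.25 * even[0]
        dx[-1] += 0.25 * odd[-1]
        return np.moveaxis(dx, 0, axis)

    def forward(self, x, train=False):
        if self.mode == "nearest":
            return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
        return self._axis_up(self._axis_up(x, 2), 3)

    def backward(self, grad):
        if self.mode == "nearest":
            C, N, H2, W2 = grad.shape
            g = grad.reshape(C, N, H2 // 2, 2, W2 // 2, 2)
            return g.sum(axis=(3, 5))
        return self._axis_down(self._axis_down(grad, 3), 2)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
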