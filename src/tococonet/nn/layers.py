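"""Differentiable layers (N×H×W×C layout) with explicit backward passes.

NHWC is used throughout because it makes the im2col patch matrix almost
contiguous on CPU (each kernel row of a patch is one contiguous 3·C run),
turning convolution into a plain GEMM whose output needs no transpose.

The default dtype is float32; :func:`set_default_dtype` switches newly
built models to float64, which the test suite uses for finite-difference
gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "BilinearUpsample2x",
    "BatchNorm2d",
    "set_default_dtype",
    "get_default_dtype",
]

_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used for parameters and buffers of newly built layers."""
    global _DEFAULT_DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("default dtype must be float32 or float64")
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


class Parameter:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    """Base class: a module owns parameters and caches its forward state.

    Each module instance appears exactly once in a computation graph, so a
    single forward cache per instance suffices for backprop.
    """

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def submodules(self) -> list["Module"]:
        out: list[Module] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
                out.extend(v.submodules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.append(item)
                        out.extend(item.submodules())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padded k×k patch matrix: (N, H, W, k²·C) from NHWC input."""
    n, h, w, c = x.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    # windows over H, W → (N, H, W, C, k, k); reorder so (i, j, c) is the
    # patch axis order, making each kernel row a contiguous 3·C memory run
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(n, h, w, k * k * c)


class Conv2d(Module):
    """Same-padded 2-D convolution (kernel 1 or 3) with bias, He-initialized.

    Weights are stored as (out_channels, k·k·in_channels) matching the
    im2col patch order (i, j, c).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv"):
        if kernel not in (1, 3):
            raise ValueError("only 1×1 and 3×3 kernels are used in these networks")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels))
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        if self.kernel == 1:
            cols = x.reshape(n, h, w, c)
        else:
            cols = _im2col(x, self.kernel)
        self._cols = cols if train else None
        out = cols.reshape(-1, cols.shape[-1]) @ self.weight.data.T + self.bias.data
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = grad.shape
        g = grad.reshape(-1, self.out_channels)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.weight.grad += g.T @ cols
        self.bias.grad += g.sum(axis=0)
        dcols = g @ self.weight.data
        self._cols = None
        k = self.kernel
        if k == 1:
            return dcols.reshape(n, h, w, self.in_channels)
        dcols = dcols.reshape(n, h, w, k, k, self.in_channels)
        p = k // 2
        dpad = np.zeros((n, h + 2 * p, w + 2 * p, self.in_channels), dtype=grad.dtype)
        # scatter-add each kernel tap back onto the padded input grid
        for i in range(k):
            for j in range(k):
                dpad[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dpad[:, p : p + h, p : p + w, :]


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2x2(Module):
    """2×2 max pooling with stride 2; ties route to the first occurrence."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2×2 pooling, got {h}×{w}")
        r = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h // 2, w // 2, 4, c)
        )
        idx = r.argmax(axis=3)
        out = np.take_along_axis(r, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._idx = idx if train else None
        self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        scat = np.zeros((n, h // 2, w // 2, 4, c), dtype=grad.dtype)
        np.put_along_axis(scat, self._idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        self._idx = None
        return (
            scat.reshape(n, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )


def _bilinear_matrix(n_in: int, dtype) -> np.ndarray:
    """(2n × n) row-interpolation matrix for exact ×2 bilinear upsampling.

    Output sample o reads source coordinate (o + 0.5)/2 − 0.5 (half-pixel
    centers), clamped at the borders.
    """
    m = np.zeros((2 * n_in, n_in), dtype=dtype)
    for o in range(2 * n_in):
        src = (o + 0.5) / 2.0 - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        m[o, i0] += 1.0 - t
        m[o, i1] += t
    return m


class BilinearUpsample2x(Module):
    """Doubles H and W by separable bilinear interpolation."""

    _cache: dict[tuple[int, str], np.ndarray] = {}

    @classmethod
    def _matrix(cls, n: int, dtype) -> np.ndarray:
        key = (n, np.dtype(dtype).name)
        if key not in cls._cache:
            cls._cache[key] = _bilinear_matrix(n, dtype)
        return cls._cache[key]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _, h, w, _ = x.shape
        mh, mw = self._matrix(h, x.dtype), self._matrix(w, x.dtype)
        self._shape = (h, w)
        y = np.einsum("oh,nhwc->nowc", mh, x, optimize=True)
        return np.einsum("pw,nowc->nopc", mw, y, optimize=True)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._shape
        mh, mw = self._matrix(h, grad.dtype), self._matrix(w, grad.dtype)
        g = np.einsum("pw,nopc->nowc", mw, grad, optimize=True)
        return np.einsum("oh,nowc->nhwc", mh, g, optimize=True)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=_DEFAULT_DTYPE)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._xhat, self._inv_std = xhat, inv_std
        else:
            self._xhat = self._inv_std = None
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.data
        mean_g = g.mean(axis=(0, 1, 2), keepdims=True)
        mean_gx = (g * xhat).mean(axis=(0, 1, 2), keepdims=True)
        self._xhat = self._inv_std = None
        return inv_std * (g - mean_g - xhat * mean_gx)
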