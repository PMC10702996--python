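"""Layer implementations (forward + manual backward), float64, NCHW."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Parameter", "Module", "Conv2d", "DepthwiseConv2d", "Linear",
    "BatchNorm2d", "ReLU", "ReLU6", "HSwish", "HSigmoid", "Sigmoid",
    "GlobalAvgPool", "Dropout", "Upsample2x", "Sequential", "h_swish",
]


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Module:
    """Base class: children discovered by attribute scan."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        if id(self) in seen:
            return
        seen.add(id(self))
        for value in vars(self).values():
            if isinstance(value, Parameter) and id(value) not in seen:
                seen.add(id(value))
                params.append(value)
            elif isinstance(value, Module):
                value._collect(params, seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._collect(params, seen)

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data[...] = arr

    def save(self, path: str) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    def forward(self, x, train: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _extract_patches(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> (B, C, Ho, Wo, k, k) view."""
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _scatter_patches(dpatches: np.ndarray, xp_shape, k: int, stride: int) -> np.ndarray:
    """Adjoint of _extract_patches: (B, C, Ho, Wo, k, k) -> (B, C, Hp, Wp)."""
    dxp = np.zeros(xp_shape)
    _, _, Ho, Wo, _, _ = dpatches.shape
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += (
                dpatches[:, :, :, :, i, j])
    return dxp


class Conv2d(Module):
    """Standard 2-D convolution via im2col.  padding defaults to k//2 ('same')."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.padding = k // 2 if padding is None else padding
        fan_in = in_ch * k * k
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, k, k), fan_in), "conv.w")
        self.bias = Parameter(np.zeros(out_ch), "conv.b") if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        p, k, s = self.padding, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        patches = _extract_patches(xp, k, s)           # (B,C,Ho,Wo,k,k)
        B_, C_, Ho, Wo, _, _ = patches.shape
        cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
        wmat = self.weight.data.reshape(self.out_ch, C * k * k)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        out = np.ascontiguousarray(out.reshape(B, Ho, Wo, self.out_ch).transpose(0, 3, 1, 2))
        self._cache = (cols, xp.shape, (B, Ho, Wo))
        return out

    def backward(self, dout):
        cols, xp_shape, (B, Ho, Wo) = self._cache
        k, s, p, C = self.k, self.stride, self.padding, self.in_ch
        dmat = dout.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, self.out_ch)
        wmat = self.weight.data.reshape(self.out_ch, C * k * k)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dmat.sum(axis=0)
        dcols = dmat @ wmat
        dpatches = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = _scatter_patches(dpatches, xp_shape, k, s)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class DepthwiseConv2d(Module):
    """Per-channel k×k convolution ('same' padding)."""

    def __init__(self, channels: int, k: int, stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels, self.k, self.stride = channels, k, stride
        self.padding = k // 2
        self.weight = Parameter(_he_init(rng, (channels, k, k), k * k), "dwconv.w")
        self.bias = Parameter(np.zeros(channels), "dwconv.b") if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        p, k, s = self.padding, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        patches = _extract_patches(xp, k, s)
        out = np.einsum("bchwij,cij->bchw", patches, self.weight.data, optimize=True)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (patches, xp.shape)
        return out

    def backward(self, dout):
        patches, xp_shape = self._cache
        self.weight.grad += np.einsum("bchw,bchwij->cij", dout, patches, optimize=True)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        dpatches = np.einsum("bchw,cij->bchwij", dout, self.weight.data, optimize=True)
        dxp = _scatter_patches(dpatches, xp_shape, self.k, self.stride)
        p = self.padding
        return dxp[:, :, p:-p, p:-p]


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (out_f, in_f), in_f), "linear.w")
        self.bias = Parameter(np.zeros(out_f), "linear.b") if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        self._cache = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, dout):
        x = self._cache
        self.weight.grad += dout.T @ x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train: bool = False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, inv_std, train, shape = self._cache
        B, C, H, W = shape
        m = B * H * W
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat * inv_std[None, :, None, None]
        sd = dxhat.sum(axis=(0, 2, 3))
        sdx = (dxhat * xhat).sum(axis=(0, 2, 3))
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat - sd[None, :, None, None] - xhat * sdx[None, :, None, None]
        )
        return dx


def h_swish(x):
    """h-swish(x) = x * ReLU6(x + 3) / 6 (works on scalars and arrays)."""
    x = np.asarray(x, dtype=np.float64)
    out = x * np.clip(x + 3.0, 0.0, 6.0) / 6.0
    return out if out.ndim else float(out)


class _Activation(Module):
    def forward(self, x, train: bool = False):
        self._cache = x
        return self._f(x)

    def backward(self, dout):
        return dout * self._df(self._cache)


class ReLU(_Activation):
    _f = staticmethod(lambda x: np.maximum(x, 0.0))
    _df = staticmethod(lambda x: (x > 0).astype(np.float64))


class ReLU6(_Activation):
    _f = staticmethod(lambda x: np.clip(x, 0.0, 6.0))
    _df = staticmethod(lambda x: ((x > 0) & (x < 6)).astype(np.float64))


class HSwish(_Activation):
    _f = staticmethod(h_swish)

    @staticmethod
    def _df(x):
        d = np.where(x < -3.0, 0.0, np.where(x > 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        return d


class HSigmoid(_Activation):
    _f = staticmethod(lambda x: np.clip(x + 3.0, 0.0, 6.0) / 6.0)
    _df = staticmethod(lambda x: ((x > -3) & (x < 3)).astype(np.float64) / 6.0)


class Sigmoid(Module):
    def forward(self, x, train: bool = False):
        out = expit(x)
        self._cache = out
        return out

    def backward(self, dout):
        s = self._cache
        return dout * s * (1.0 - s)


class GlobalAvgPool(Module):
    """(B, C, H, W) -> (B, C)."""

    def forward(self, x, train: bool = False):
        self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        B, C, H, W = self._cache
        return np.broadcast_to(dout[:, :, None, None], (B, C, H, W)) / (H * W)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout fraction must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def _upsample_matrix(n: int, mode: str) -> np.ndarray:
    """(2n, n) interpolation matrix for one axis (align_corners=False)."""
    U = np.zeros((2 * n, n))
    if mode == "nearest":
        for o in range(2 * n):
            U[o, o // 2] = 1.0
        return U
    for o in range(2 * n):
        c = (o + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(c))
        w1 = c - i0
        i0c = min(max(i0, 0), n - 1)
        i1c = min(max(i0 + 1, 0), n - 1)
        U[o, i0c] += 1.0 - w1
        U[o, i1c] += w1
    return U


class Upsample2x(Module):
    """Fixed ×2 spatial upsampling, 'nearest' or 'bilinear'."""

    def __init__(self, mode: str = "bilinear"):
        if mode not in ("nearest", "bilinear"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        self.mode = mode
        self._mats: dict[int, np.ndarray] = {}

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _upsample_matrix(n, self.mode)
        return self._mats[n]

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        Uh, Uw = self._mat(H), self._mat(W)
        self._cache = (Uh, Uw)
        return np.einsum("oh,bchw,pw->bcop", Uh, x, Uw, optimize=True)

    def backward(self, dout):
        Uh, Uw = self._cache
        return np.einsum("oh,bcop,pw->bchw", Uh, dout, Uw, optimize=True)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
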