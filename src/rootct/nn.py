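"""A small 3-D convolutional network engine on numpy.

Implements exactly the pieces the segmentation/restoration networks need:
3-D convolution (stride 1 or 2) via im2col + BLAS matmul, 2x transposed
convolution, batch normalisation, ReLU/sigmoid, and the Adam optimiser.
Every layer provides an analytic ``backward``; the gradients are verified
against central finite differences in the test suite.

Arrays are laid out ``(N, C, H, W, D)``.  The default parameter dtype is
float32; float64 is supported (and used for gradient checks).
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "Adam",
]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Module:
    """Base class: forward caches what backward needs; params are listed
    in a deterministic order so checkpoints and optimisers stay aligned."""

    def walk(self):
        """Yield this module and every descendant."""
        yield self

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-learnable state (e.g. batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def walk(self):
        yield self
        for m in self.modules:
            yield from m.walk()

    def params(self) -> list[Param]:
        return [p for m in self.modules for p in m.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for m in self.modules for b in m.buffers()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv3d(Module):
    """3-D convolution with 'same'-style zero padding (pad = kernel//2).

    Lowered to a single BLAS matmul per pass: the im2col buffer is laid
    out ``(C*k^3, N*Ho*Wo*Do)`` and filled by ``C*k^3`` contiguous slice
    copies, which is much faster than gathering a transposed window view.
    The buffer is rebuilt in backward rather than cached, trading a cheap
    copy for a large peak-memory saving.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        #: set on the first layer of a network: its input gradient is
        #: never consumed, so the col2im scatter can be skipped
        self.skip_input_grad = False
        fan_in = in_ch * kernel**3
        self.weight = Param(
            _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in, dtype),
            "conv.weight",
        )
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "conv.bias")
        self._xp: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _out_sides(self, spatial):
        k, s, p = self.kernel, self.stride, self.pad
        return tuple((n + 2 * p - k) // s + 1 for n in spatial)

    def _fill_cols(self, xp: np.ndarray, out_sides, cols: np.ndarray) -> None:
        k, s = self.kernel, self.stride
        N = xp.shape[0]
        Ho, Wo, Do = out_sides
        r = 0
        for ch in range(self.in_ch):
            for a, b, c in product(range(k), repeat=3):
                view = xp[
                    :,
                    ch,
                    a : a + s * (Ho - 1) + 1 : s,
                    b : b + s * (Wo - 1) + 1 : s,
                    c : c + s * (Do - 1) + 1 : s,
                ]
                np.copyto(cols[r].reshape(N, Ho, Wo, Do), view)
                r += 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W, D = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        p = self.pad
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        )
        self._xp, self._in_shape = xp, x.shape
        Ho, Wo, Do = self._out_sides((H, W, D))
        wmat = self.weight.value.reshape(self.out_ch, -1)
        if self.kernel == 1 and self.stride == 1:
            rows = xp.reshape(N, C, -1)
            y = np.einsum("oc,ncr->nor", wmat, rows, optimize=True)
            y += self.bias.value[None, :, None]
            return np.ascontiguousarray(
                y.reshape(N, self.out_ch, Ho, Wo, Do)
            )
        cols = np.empty((C * self.kernel**3, N * Ho * Wo * Do), dtype=x.dtype)
        self._fill_cols(xp, (Ho, Wo, Do), cols)
        y = wmat @ cols
        y += self.bias.value[:, None]
        y = y.reshape(self.out_ch, N, Ho, Wo, Do).transpose(1, 0, 2, 3, 4)
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, in_shape = self._xp, self._in_shape
        assert xp is not None, "backward called before forward"
        N, C, H, W, D = in_shape
        k, s, p = self.kernel, self.stride, self.pad
        Ho, Wo, Do = self._out_sides((H, W, D))
        wmat = self.weight.value.reshape(self.out_ch, -1)
        grows = np.ascontiguousarray(
            grad.transpose(1, 0, 2, 3, 4).reshape(self.out_ch, -1)
        )
        self.bias.grad += grows.sum(axis=1)
        if k == 1 and s == 1:
            rows = xp.reshape(N, C, -1)
            xmat = rows.transpose(1, 0, 2).reshape(C, -1)
            self.weight.grad += (grows @ xmat.T).reshape(self.weight.value.shape)
            dx = (wmat.T @ grows).reshape(C, N, H, W, D).transpose(1, 0, 2, 3, 4)
            return np.ascontiguousarray(dx)
        cols = np.empty((C * k**3, N * Ho * Wo * Do), dtype=grad.dtype)
        self._fill_cols(xp, (Ho, Wo, Do), cols)
        self.weight.grad += (grows @ cols.T).reshape(self.weight.value.shape)
        del cols
        if self.skip_input_grad:
            return np.zeros(in_shape, dtype=grad.dtype)
        dcols = wmat.T @ grows
        dxp = np.zeros_like(xp)
        r = 0
        for ch in range(C):
            for a, b, c in product(range(k), repeat=3):
                dxp[
                    :,
                    ch,
                    a : a + s * (Ho - 1) + 1 : s,
                    b : b + s * (Wo - 1) + 1 : s,
                    c : c + s * (Do - 1) + 1 : s,
                ] += dcols[r].reshape(N, Ho, Wo, Do)
                r += 1
        if p:
            return np.ascontiguousarray(dxp[:, :, p : p + H, p : p + W, p : p + D])
        return dxp


class ConvTranspose3d(Module):
    """2x up-sampling transposed convolution (kernel 2, stride 2)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(
            _he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch, dtype), "deconv.weight"
        )
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "deconv.bias")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        N, C, H, W, D = x.shape
        wmat = self.weight.value.reshape(C, -1)  # (Cin, Cout*8)
        out = np.empty((N, self.out_ch, 2 * H, 2 * W, 2 * D), dtype=x.dtype)
        for n in range(N):
            rows = x[n].reshape(C, -1).T  # (HWD, Cin)
            blocks = (rows @ wmat).reshape(H, W, D, self.out_ch, 2, 2, 2)
            for a, b, c in product(range(2), repeat=3):
                out[n, :, a::2, b::2, c::2] = blocks[..., a, b, c].transpose(
                    3, 0, 1, 2
                )
            out[n] += self.bias.value[:, None, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        N, C, H, W, D = x.shape
        wmat = self.weight.value.reshape(C, -1)
        dx = np.empty_like(x)
        dW = np.zeros_like(wmat)
        for n in range(N):
            blocks = np.empty((H, W, D, self.out_ch, 2, 2, 2), dtype=grad.dtype)
            for a, b, c in product(range(2), repeat=3):
                blocks[..., a, b, c] = grad[n, :, a::2, b::2, c::2].transpose(
                    1, 2, 3, 0
                )
            grows = blocks.reshape(-1, self.out_ch * 8)  # (HWD, Cout*8)
            rows = x[n].reshape(C, -1).T
            dW += rows.T @ grows
            dx[n] = (grows @ wmat.T).T.reshape(C, H, W, D)
        self.weight.grad += dW.reshape(self.weight.value.shape)
        self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        return dx


class BatchNorm3d(Module):
    """Batch normalisation over (N, H, W, D) per channel.

    Training uses batch statistics and updates exponential running
    averages (momentum 0.1); evaluation uses the running averages.
    """

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.ch = ch
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(ch, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        sh = (1, self.ch, 1, 1, 1)
        xhat = (x - mean.reshape(sh)) * ivar.reshape(sh)
        self._cache = (xhat, ivar, train)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, ivar, train = self._cache
        sh = (1, self.ch, 1, 1, 1)
        axes = (0, 2, 3, 4)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value.reshape(sh)
        if not train:
            return dxhat * ivar.reshape(sh)
        # standard batch-norm backward, vectorised per channel
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh)
        )
        return term * ivar.reshape(sh)


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0)


class Sigmoid(Module):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y = self._y
        return grad * y * (1.0 - y)


class Adam:
    """Adam with the usual bias-corrected first/second moment estimates."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
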