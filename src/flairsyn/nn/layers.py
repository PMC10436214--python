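"""Minimal reverse-mode neural-network layers on numpy arrays.

All layers operate on batches in ``(N, C, H, W)`` layout.  Each layer caches
the context of every ``forward`` call on a stack and pops it in ``backward``,
so a module may appear several times in one computation graph (as the
CycleGAN generators do) provided backward calls happen in exact reverse
order of the forward calls.  Gradients accumulate into ``Parameter.grad``
until ``zero_grad`` is called.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "InstanceNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "GaussianNoise",
    "Upsample2d",
]


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base layer: forward/backward with a LIFO context stack."""

    def __init__(self):
        self.training = True
        self._ctx: list = []

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for attr in vars(self).values():
            if isinstance(attr, Module):
                out.extend(attr.modules())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def clear_context(self) -> None:
        """Drop cached forward contexts (after forward passes that won't be
        followed by a backward, e.g. inference or discriminator-frozen passes)."""
        for m in self.modules():
            m._ctx.clear()

    def eval(self) -> "Module":
        return self.train(False)

    # -- forward/backward ---------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def _buffer_refs(self) -> list[tuple["Module", str]]:
        """(module, attribute) pairs of non-trainable state (e.g. batch-norm
        running statistics) that checkpoints must carry."""
        refs = []
        for m in self.modules():
            for name in getattr(m, "_buffers", ()):
                refs.append((m, name))
        return refs

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and buffers (for checkpoints)."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        for j, (m, name) in enumerate(self._buffer_refs()):
            arrays[f"b{j}"] = getattr(m, name)
        return arrays

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        buffers = self._buffer_refs()
        if len(state) != len(params) + len(buffers):
            raise ValueError(
                f"checkpoint holds {len(state)} arrays, module has "
                f"{len(params)} parameters + {len(buffers)} buffers"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value = arr.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        for j, (m, name) in enumerate(buffers):
            setattr(m, name, np.asarray(state[f"b{j}"], dtype=np.float64))

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, k, k, oh, ow) view-copy of sliding windows."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols


class Conv2d(Module):
    """2-D convolution (cross-correlation) with im2col forward/backward.

    ``weight_scale`` lets a wrapper (spectral normalization) rescale the
    effective weight without touching the raw parameter; the chain rule for
    the raw weight then just multiplies the gradient by the same scale.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(
            rng.normal(0.0, init_std, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.weight_scale = 1.0

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"convolution input {h}x{w} too small for kernel {k} (stride {s}, padding {p})"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s, oh, ow).reshape(n, c * k * k, oh * ow)
        w_eff = (self.weight.value * self.weight_scale).reshape(self.out_channels, -1)
        out = np.einsum("of,nfl->nol", w_eff, cols, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._ctx.append((cols, x.shape, oh, ow, self.weight_scale))
        return out.reshape(n, self.out_channels, oh, ow)

    def backward(self, grad):
        cols, x_shape, oh, ow, scale = self._ctx.pop()
        n, c, h, w = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        g = grad.reshape(n, self.out_channels, oh * ow)
        dw_eff = np.einsum("nol,nfl->of", g, cols, optimize=True)
        self.weight.grad += (scale * dw_eff).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        w_eff = (self.weight.value * scale).reshape(self.out_channels, -1)
        dcols = np.einsum("of,nol->nfl", w_eff, g, optimize=True)
        dcols = dcols.reshape(n, c, k, k, oh, ow)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over spatial dims with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._ctx.append((xhat, inv_std))
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std = self._ctx.pop()
        m = xhat.shape[2] * xhat.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        term = (
            m * dxhat
            - dxhat.sum(axis=(2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        )
        return inv_std / m * term


class BatchNorm2d(Module):
    """Per-channel normalization over the batch and spatial dims.

    Unlike instance norm, batch statistics preserve each sample's absolute
    intensity level relative to the batch — which matters when the target
    depends on absolute intensities, as in intensity-mapped translation.
    Evaluation mode uses running statistics (exponential average,
    momentum 0.1), carried in checkpoints as buffers.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._ctx.append((xhat, inv_std, self.training))
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std, was_training = self._ctx.pop()
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        if not was_training:  # running stats are constants
            return dxhat * inv_std[None, :, None, None]
        m = xhat.shape[0] * xhat.shape[2] * xhat.shape[3]
        term = (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        return inv_std[None, :, None, None] / m * term


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        mask = x >= 0
        self._ctx.append(mask)
        return np.where(mask, x, self.alpha * x)

    def backward(self, grad):
        mask = self._ctx.pop()
        return np.where(mask, grad, self.alpha * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Module):
    def forward(self, x):
        y = np.tanh(x)
        self._ctx.append(y)
        return y

    def backward(self, grad):
        y = self._ctx.pop()
        return grad * (1.0 - y * y)


class GaussianNoise(Module):
    """Additive zero-mean Gaussian noise, active only in training mode."""

    def __init__(self, sd: float, rng: np.random.Generator | None = None):
        super().__init__()
        if sd < 0:
            raise ValueError("noise sd must be nonnegative")
        self.sd = sd
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if self.training and self.sd > 0:
            return x + self.rng.normal(0.0, self.sd, x.shape)
        return x

    def backward(self, grad):
        return grad


class Upsample2d(Module):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        f = self.factor
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, grad):
        f = self.factor
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))
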