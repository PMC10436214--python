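"""Spectral normalization: weight / sigma_max via power iteration.

Dividing a layer's weight matrix by its largest singular value bounds the
layer's Lipschitz constant by 1, which stabilizes GAN discriminators and
mitigates mode collapse.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import DegenerateInputError
from .layers import Conv2d, Module

__all__ = ["spectral_normalize", "estimate_sigma_max", "SpectralNormConv2d"]

_EPS = 1e-12


def estimate_sigma_max(
    weight: np.ndarray,
    n_iters: int = 1,
    u: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Power-iteration estimate of the largest singular value of a 2-D matrix.

    Returns ``(sigma, u, v)`` where ``u``/``v`` are the left/right singular
    vector estimates; passing the previous ``u`` back in ("persistent
    iteration vectors") makes one iteration per training step sufficient.
    """
    w = np.asarray(weight, dtype=np.float64)
    if w.ndim != 2:
        raise ValueError("weight must be a 2-D matrix")
    if u is None:
        u = np.random.default_rng(0).normal(size=w.shape[0])
    v = np.zeros(w.shape[1])
    for _ in range(max(1, n_iters)):
        v = w.T @ u
        v = v / (np.linalg.norm(v) + _EPS)
        u = w @ v
        u = u / (np.linalg.norm(u) + _EPS)
    sigma = float(u @ w @ v)
    return sigma, u, v


def spectral_normalize(weight: np.ndarray, n_iters: int = 20) -> np.ndarray:
    """Return ``weight / sigma_max(weight)`` with sigma_max from power iteration.

    The input is the 2-D coefficient matrix of a layer (a convolution kernel
    reshaped to ``(out_channels, in_channels * k * k)``).  After
    normalization the largest singular value is 1 up to the power-iteration
    tolerance.

    Raises
    ------
    DegenerateInputError
        If the weight matrix is identically zero.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    w = np.asarray(weight, dtype=np.float64)
    if not np.any(w):
        raise DegenerateInputError("cannot spectrally normalize an all-zero weight")
    sigma, _, _ = estimate_sigma_max(w, n_iters=n_iters)
    return w / max(sigma, _EPS)


class SpectralNormConv2d(Module):
    """Conv2d whose effective weight is divided by its largest singular value.

    One power iteration per forward pass with a persistent ``u`` vector.  The
    backward pass treats the estimated sigma as a constant (the iteration
    vectors are detached), so the raw-weight gradient is the normalized-weight
    gradient divided by sigma; ``Conv2d.weight_scale`` implements exactly that.
    """

    def __init__(self, conv: Conv2d, n_iters: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if n_iters < 1:
            raise ValueError("n_iters must be >= 1 when spectral normalization is on")
        self.conv = conv
        self.n_iters = n_iters
        rng = rng or np.random.default_rng(0)
        self.u = rng.normal(size=conv.out_channels)

    def forward(self, x):
        w2 = self.conv.weight.value.reshape(self.conv.out_channels, -1)
        if self.training:
            sigma, self.u, _ = estimate_sigma_max(w2, n_iters=self.n_iters, u=self.u)
        else:
            # evaluation: reuse the stored iteration vector, don't update it
            v = w2.T @ self.u
            v = v / (np.linalg.norm(v) + _EPS)
            sigma = float(self.u @ w2 @ v / (np.linalg.norm(self.u) + _EPS))
        self.conv.weight_scale = 1.0 / max(abs(sigma), _EPS)
        return self.conv.forward(x)

    def backward(self, grad):
        return self.conv.backward(grad)
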