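"""Feature embedders for FID computation.

The FID contract only needs a map from image slices to fixed-length
feature vectors.  The production choice in the literature is a pretrained
medical-imaging network; here the embedder is injected, and the package
ships a fixed-seed random-projection convolutional embedder whose random
filters are frozen at construction.  Random convolutional features
preserve enough distributional structure for the Fréchet distance to
order "identical distribution" below "shifted distribution", which is
what in-training epoch selection requires at desk scale.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, LeakyReLU, Sequential

__all__ = ["RandomConvEmbedder", "Embedder"]

from typing import Protocol


class Embedder(Protocol):
    """Anything mapping an (n, H, W) stack of slices to (n, dim) features."""

    def __call__(self, images: np.ndarray) -> np.ndarray: ...


class RandomConvEmbedder:
    """Frozen random convolutional feature extractor.

    Three stride-2 convolutions with leaky-ReLU nonlinearities followed by
    global mean and standard-deviation pooling per channel.  Deterministic
    for a fixed seed; never trained.
    """

    def __init__(self, channels: tuple[int, ...] = (8, 16, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        layers = []
        prev = 1
        for ch in channels:
            layers += [Conv2d(prev, ch, 3, stride=2, padding=1, rng=rng, init_std=0.5), LeakyReLU(0.2)]
            prev = ch
        self.net = Sequential(*layers).eval()
        self.n_features = 2 * channels[-1]

    def __call__(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        feats = []
        for i in range(0, len(images), 32):
            h = self.net.forward(images[i : i + 32, None])
            feats.append(
                np.concatenate([h.mean(axis=(2, 3)), h.std(axis=(2, 3))], axis=1)
            )
        self.net.clear_context()
        return np.concatenate(feats, axis=0)
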