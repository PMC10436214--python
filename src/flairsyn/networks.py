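"""Model families: U-Net and ResNet generators, PatchGAN discriminators.

Four bundles are available:

* ``pix2pix`` — U-Net generator + conditional PatchGAN discriminator,
* ``cyclegan_paired`` / ``cyclegan_unpaired`` — two ResNet encoder-decoder
  generators + two PatchGAN discriminators, optionally "modified" with
  spectral normalization and training-time Gaussian noise to mitigate mode
  collapse,
* ``autoencoder`` — the U-Net generator with every skip connection removed
  (same hidden layer stack), trained without a discriminator.

All generators are shape-preserving and end in tanh, matching data
normalized to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .nn import (
    BatchNorm2d,
    Conv2d,
    GaussianNoise,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ReLU,
    Sequential,
    SpectralNormConv2d,
    Tanh,
    Upsample2d,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "ModelBundle",
    "UNetGenerator",
    "ResNetGenerator",
    "PatchGANDiscriminator",
    "build_unet_generator",
    "build_resnet_generator",
    "build_patchgan_discriminator",
    "build_autoencoder",
    "build_model_bundle",
    "default_unet_depth",
    "default_resnet_blocks",
]

MODEL_FAMILIES = ("pix2pix", "cyclegan_paired", "cyclegan_unpaired", "autoencoder")


@dataclass
class GeneratorSpec:
    """Architecture description of one generator."""

    family: str = "unet"  # "unet" | "resnet"
    input_shape: tuple[int, int, int] = (256, 256, 1)  # (rows, cols, channels)
    base_filters: int = 64
    n_resnet_blocks: int | None = None  # resnet only; None -> size-dependent default
    skip_connections: bool = True  # unet only; False -> autoencoder
    depth: int | None = None  # unet only; None -> down to a 1x1 bottleneck
    out_channels: int = 1

    def __post_init__(self):
        if self.family not in ("unet", "resnet"):
            raise ConfigurationError(f"unknown generator family {self.family!r}")
        if self.base_filters < 1:
            raise ConfigurationError("base_filters must be >= 1")


@dataclass
class DiscriminatorSpec:
    """Architecture description of one PatchGAN discriminator."""

    input_shape: tuple[int, int, int] = (256, 256, 1)
    base_filters: int = 64
    n_layers: int = 3  # stride-2 downsampling convolutions (70x70 receptive field)
    modified: bool = False  # spectral norm + Gaussian noise
    noise_sd: float = 0.1
    spectral_norm_iters: int = 1
    norm: str = "instance"  # "instance" (CycleGAN) | "batch" (pix2pix)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.modified and self.spectral_norm_iters < 1:
            raise ConfigurationError("spectral_norm_iters must be >= 1 when modified")


@dataclass
class ModelBundle:
    """Generators and discriminators of one model family."""

    family: str
    generators: list = field(default_factory=list)
    discriminators: list = field(default_factory=list)

    def __post_init__(self):
        expected = {
            "pix2pix": (1, 1),
            "cyclegan_paired": (2, 2),
            "cyclegan_unpaired": (2, 2),
            "autoencoder": (1, 0),
        }
        if self.family not in expected:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        ng, nd = expected[self.family]
        if len(self.generators) != ng or len(self.discriminators) != nd:
            raise ConfigurationError(
                f"{self.family} requires {ng} generator(s) and {nd} discriminator(s)"
            )

    def modules(self) -> list[Module]:
        return list(self.generators) + list(self.discriminators)


def default_unet_depth(spatial: tuple[int, int]) -> int:
    """Depth that downsamples the smaller spatial dimension to 1 (capped at 8)."""
    m = min(spatial)
    depth = int(np.log2(m))
    if 2**depth != m:
        raise ConfigurationError(f"spatial dims {spatial} are not a power of two; pass depth explicitly")
    return min(depth, 8)


def default_resnet_blocks(spatial: tuple[int, int]) -> int:
    """9 residual blocks at >=256 resolution, 6 below (canonical configuration)."""
    return 9 if min(spatial) >= 256 else 6


def _filters(base: int, level: int) -> int:
    return base * min(2 ** (level - 1), 8)


class UNetGenerator(Module):
    """Encoder-decoder with optional skip concatenations.

    Encoder blocks are 4x4 stride-2 convolutions (instance norm on all but
    the outermost and the bottleneck layer), decoder blocks are nearest
    upsampling followed by a 3x3 convolution.  With ``skip=False`` the layer
    stack is identical but the concatenations are removed — that variant is
    the convolutional autoencoder ablation.
    """

    def __init__(
        self,
        in_channels: int = 1,
        out_channels: int = 1,
        base_filters: int = 64,
        depth: int = 8,
        skip: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if depth < 2:
            raise ConfigurationError("U-Net depth must be >= 2")
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.skip = skip
        f = [_filters(base_filters, i) for i in range(1, depth + 1)]
        self.enc_blocks: list[Module] = []
        prev = in_channels
        for i in range(1, depth + 1):
            layers: list[Module] = [Conv2d(prev, f[i - 1], 4, stride=2, padding=1, rng=rng)]
            if 1 < i < depth:
                layers.append(BatchNorm2d(f[i - 1]))
            layers.append(LeakyReLU(0.2))
            self.enc_blocks.append(Sequential(*layers))
            prev = f[i - 1]
        self.dec_blocks: list[Module] = []
        for i in range(depth, 0, -1):
            in_ch = f[i - 1] if i == depth else (2 * f[i - 1] if skip else f[i - 1])
            out_ch = f[i - 2] if i >= 2 else base_filters
            self.dec_blocks.append(
                Sequential(
                    Upsample2d(2),
                    Conv2d(in_ch, out_ch, 3, stride=1, padding=1, rng=rng),
                    BatchNorm2d(out_ch),
                    ReLU(),
                )
            )
        self.head = Sequential(Conv2d(base_filters, out_channels, 3, stride=1, padding=1, rng=rng), Tanh())

    def forward(self, x):
        feats = []
        h = x
        for blk in self.enc_blocks:
            h = blk.forward(h)
            feats.append(h)
        y = feats[-1]
        for j, blk in enumerate(self.dec_blocks):
            level = self.depth - j  # block consumes features at res / 2^level
            if level < self.depth and self.skip:
                y = np.concatenate([y, feats[level - 1]], axis=1)
            y = blk.forward(y)
        self._ctx.append(None)
        return self.head.forward(y)

    def backward(self, grad):
        self._ctx.pop()
        g = self.head.backward(grad)
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            level = self.depth - j
            g = self.dec_blocks[j].backward(g)
            if level < self.depth and self.skip:
                out_prev = g.shape[1] // 2
                skip_grads[level] = g[:, out_prev:]
                g = g[:, :out_prev]
        for i in range(self.depth, 0, -1):
            if i < self.depth and self.skip:
                g = g + skip_grads[i]
            g = self.enc_blocks[i - 1].backward(g)
        return g


class ResnetBlock(Module):
    """Identity-plus-transform residual block (two 3x3 convolutions)."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.branch = Sequential(
            Conv2d(channels, channels, 3, stride=1, padding=1, rng=rng),
            InstanceNorm2d(channels),
            ReLU(),
            Conv2d(channels, channels, 3, stride=1, padding=1, rng=rng),
            InstanceNorm2d(channels),
        )

    def forward(self, x):
        return x + self.branch.forward(x)

    def backward(self, grad):
        return grad + self.branch.backward(grad)


class ResNetGenerator(Module):
    """c7s1 stem, two stride-2 downsamplers, residual blocks, two upsamplers."""

    def __init__(
        self,
        in_channels: int = 1,
        out_channels: int = 1,
        base_filters: int = 64,
        n_blocks: int = 9,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if n_blocks < 1:
            raise ConfigurationError("n_resnet_blocks must be >= 1")
        rng = rng or np.random.default_rng(0)
        bf = base_filters
        layers: list[Module] = [
            Conv2d(in_channels, bf, 7, stride=1, padding=3, rng=rng),
            InstanceNorm2d(bf),
            ReLU(),
            Conv2d(bf, 2 * bf, 3, stride=2, padding=1, rng=rng),
            InstanceNorm2d(2 * bf),
            ReLU(),
            Conv2d(2 * bf, 4 * bf, 3, stride=2, padding=1, rng=rng),
            InstanceNorm2d(4 * bf),
            ReLU(),
        ]
        layers += [ResnetBlock(4 * bf, rng=rng) for _ in range(n_blocks)]
        layers += [
            Upsample2d(2),
            Conv2d(4 * bf, 2 * bf, 3, stride=1, padding=1, rng=rng),
            InstanceNorm2d(2 * bf),
            ReLU(),
            Upsample2d(2),
            Conv2d(2 * bf, bf, 3, stride=1, padding=1, rng=rng),
            InstanceNorm2d(bf),
            ReLU(),
            Conv2d(bf, out_channels, 7, stride=1, padding=3, rng=rng),
            Tanh(),
        ]
        self.net = Sequential(*layers)

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, grad):
        return self.net.backward(grad)


class PatchGANDiscriminator(Module):
    """Convolutional classifier emitting a spatial grid of patch scores (logits).

    ``modified=True`` wraps every convolution in spectral normalization and
    injects additive Gaussian noise before each layer at training time only.
    """

    def __init__(
        self,
        in_channels: int = 1,
        base_filters: int = 64,
        n_layers: int = 3,
        modified: bool = False,
        noise_sd: float = 0.1,
        spectral_norm_iters: int = 1,
        norm: str = "instance",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.modified = modified
        norm_layer = BatchNorm2d if norm == "batch" else InstanceNorm2d

        def conv(cin, cout, stride):
            c = Conv2d(cin, cout, 4, stride=stride, padding=1, rng=rng)
            if modified:
                return SpectralNormConv2d(c, n_iters=spectral_norm_iters, rng=rng)
            return c

        def noise():
            return [GaussianNoise(noise_sd, rng=np.random.default_rng(rng.integers(2**31)))] if modified else []

        layers: list[Module] = []
        prev = in_channels
        nf = base_filters
        layers += noise() + [conv(prev, nf, 2), LeakyReLU(0.2)]
        prev = nf
        for _ in range(1, n_layers):
            nf = min(2 * nf, 8 * base_filters)
            layers += noise() + [conv(prev, nf, 2), norm_layer(nf), LeakyReLU(0.2)]
            prev = nf
        nf = min(2 * nf, 8 * base_filters)
        layers += noise() + [conv(prev, nf, 1), norm_layer(nf), LeakyReLU(0.2)]
        layers += noise() + [conv(nf, 1, 1)]
        self.net = Sequential(*layers)

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, grad):
        return self.net.backward(grad)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _check_unet_dims(spec: GeneratorSpec, depth: int) -> None:
    m, n = spec.input_shape[:2]
    if m % 2**depth or n % 2**depth:
        raise ConfigurationError(
            f"spatial dims {m}x{n} must be divisible by 2^depth = {2**depth}"
        )


def build_unet_generator(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> UNetGenerator:
    """U-Net generator with skip connections (the pix2pix generator)."""
    if spec.family != "unet":
        raise ConfigurationError("build_unet_generator requires family='unet'")
    depth = spec.depth if spec.depth is not None else default_unet_depth(spec.input_shape[:2])
    _check_unet_dims(spec, depth)
    return UNetGenerator(
        in_channels=spec.input_shape[2],
        out_channels=spec.out_channels,
        base_filters=spec.base_filters,
        depth=depth,
        skip=spec.skip_connections,
        rng=rng,
    )


def build_autoencoder(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> UNetGenerator:
    """Skip-free variant of the U-Net generator (identical hidden layer stack)."""
    if spec.skip_connections:
        raise ConfigurationError("autoencoder spec must have skip_connections=False")
    depth = spec.depth if spec.depth is not None else default_unet_depth(spec.input_shape[:2])
    _check_unet_dims(spec, depth)
    return UNetGenerator(
        in_channels=spec.input_shape[2],
        out_channels=spec.out_channels,
        base_filters=spec.base_filters,
        depth=depth,
        skip=False,
        rng=rng,
    )


def build_resnet_generator(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> ResNetGenerator:
    """ResNet encoder-decoder generator (the CycleGAN generator)."""
    if spec.family != "resnet":
        raise ConfigurationError("build_resnet_generator requires family='resnet'")
    m, n = spec.input_shape[:2]
    if m % 4 or n % 4:
        raise ConfigurationError("resnet generator needs spatial dims divisible by 4")
    n_blocks = (
        spec.n_resnet_blocks
        if spec.n_resnet_blocks is not None
        else default_resnet_blocks(spec.input_shape[:2])
    )
    return ResNetGenerator(
        in_channels=spec.input_shape[2],
        out_channels=spec.out_channels,
        base_filters=spec.base_filters,
        n_blocks=n_blocks,
        rng=rng,
    )


def build_patchgan_discriminator(
    spec: DiscriminatorSpec, rng: np.random.Generator | None = None
) -> PatchGANDiscriminator:
    return PatchGANDiscriminator(
        in_channels=spec.input_shape[2],
        base_filters=spec.base_filters,
        n_layers=spec.n_layers,
        modified=spec.modified,
        noise_sd=spec.noise_sd,
        spectral_norm_iters=spec.spectral_norm_iters,
        norm=spec.norm,
        rng=rng,
    )


def build_model_bundle(
    family: str,
    image_shape: tuple[int, int],
    base_filters: int = 64,
    depth: int | None = None,
    n_resnet_blocks: int | None = None,
    modified_discriminator: bool | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ModelBundle:
    """Construct the generators/discriminators of one model family.

    The pix2pix discriminator is conditional (it sees source and target
    concatenated on the channel axis); the CycleGAN discriminators are
    unconditional, one per domain.  CycleGAN discriminators default to the
    modified (spectral norm + noise) variant.
    """
    if family not in MODEL_FAMILIES:
        raise ConfigurationError(f"unknown model family {family!r}")
    rng = np.random.default_rng(seed)
    m, n = image_shape
    # the canonical 3-layer (70x70) PatchGAN needs >= 32 px; shrink for tiny inputs
    disc_layers = max(1, min(3, int(np.log2(min(m, n))) - 2))
    if family in ("pix2pix", "autoencoder"):
        gspec = GeneratorSpec(
            family="unet",
            input_shape=(m, n, 1),
            base_filters=base_filters,
            depth=depth,
            skip_connections=(family == "pix2pix"),
        )
        gen = build_unet_generator(gspec, rng=rng) if family == "pix2pix" else build_autoencoder(gspec, rng=rng)
        if family == "autoencoder":
            return ModelBundle(family, [gen], [])
        dspec = DiscriminatorSpec(
            input_shape=(m, n, 2),
            base_filters=base_filters,
            n_layers=disc_layers,
            modified=bool(modified_discriminator),
            noise_sd=noise_sd,
            norm="batch",
        )
        return ModelBundle(family, [gen], [build_patchgan_discriminator(dspec, rng=rng)])
    # cyclegan families
    gspec = GeneratorSpec(
        family="resnet",
        input_shape=(m, n, 1),
        base_filters=base_filters,
        n_resnet_blocks=n_resnet_blocks,
    )
    modified = True if modified_discriminator is None else modified_discriminator
    dspec = DiscriminatorSpec(
        input_shape=(m, n, 1),
        base_filters=base_filters,
        n_layers=disc_layers,
        modified=modified,
        noise_sd=noise_sd,
    )
    g = build_resnet_generator(gspec, rng=rng)
    f = build_resnet_generator(gspec, rng=rng)
    d_y = build_patchgan_discriminator(dspec, rng=rng)
    d_x = build_patchgan_discriminator(dspec, rng=rng)
    return ModelBundle(family, [g, f], [d_x, d_y])
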