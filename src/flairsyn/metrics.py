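"""Image-quality metrics for synthetic-vs-real comparison.

Two metric groups are implemented: human-perception metrics (PSNR, SSIM)
and structural metrics (MSE and Hist-KL, the KL divergence between the
intensity histograms of a real and a generated image).  Hist-KL is
sensitive to tissue-proportion errors — e.g. a generation that inflates
the CSF-like class — that window-averaged perceptual metrics barely
register, because any over- or under-represented tissue class shifts mass
between histogram peaks.

The Fréchet distance between Gaussian fits of embedded image features
(the core of FID) also lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import ContractError, DegenerateInputError

__all__ = [
    "MetricConfig",
    "HistogramDistribution",
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "image_histogram",
    "hist_kl",
    "frechet_distance",
    "metric_report",
]


@dataclass
class MetricConfig:
    """Shared configuration for all metrics.

    ``data_range`` is the intensity dynamic range L (2 for data normalized
    to [-1, 1]); it is the PSNR peak and sets the SSIM stabilizing
    constants C1 = (0.01 L)^2, C2 = (0.03 L)^2, C3 = C2 / 2.
    """

    data_range: float = 2.0
    ssim_exponents: tuple[float, float, float] = (1.0, 1.0, 1.0)  # alpha, beta, gamma
    ssim_constants: tuple[float, float, float] | None = None  # C1, C2, C3; None -> from data_range
    ssim_mode: str = "global"  # "global" | "windowed"
    window_size: int = 7
    hist_bins: int = 256
    hist_range: tuple[float, float] = (-1.0, 1.0)
    hist_epsilon: float = 1e-10
    exclude_background: bool = False

    def __post_init__(self):
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")
        if self.hist_bins < 2:
            raise ValueError("hist_bins must be >= 2")
        if self.hist_epsilon <= 0:
            raise ValueError("hist_epsilon must be positive")
        if self.ssim_mode not in ("global", "windowed"):
            raise ValueError(f"unknown ssim_mode {self.ssim_mode!r}")

    @property
    def constants(self) -> tuple[float, float, float]:
        if self.ssim_constants is not None:
            return self.ssim_constants
        c1 = (0.01 * self.data_range) ** 2
        c2 = (0.03 * self.data_range) ** 2
        return c1, c2, c2 / 2.0


@dataclass
class HistogramDistribution:
    """A normalized intensity histogram (a discrete probability distribution)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ContractError("probabilities must have one entry per bin")
        if np.any(self.probabilities < 0):
            raise ContractError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ContractError("probabilities must sum to 1")


@dataclass
class MetricReport:
    """Per image-pair metric record."""

    psnr_db: float
    ssim: float
    mse: float
    hist_kl: float
    region_label: str | None = None
    slice_index: int | None = None
    extras: dict = field(default_factory=dict)


def _validated_pair(x, y, mask=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ContractError(f"shape mismatch {x.shape} vs {y.shape}")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != x.shape:
            raise ContractError("mask shape must match image shape")
        if not mask.any():
            raise DegenerateInputError("mask selects no pixels")
    return x, y, mask


def mse(x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean squared difference over all (or mask-interior) pixels."""
    x, y, mask = _validated_pair(x, y, mask)
    d = (x - y) ** 2
    return float(d[mask].mean()) if mask is not None else float(d.mean())


def psnr(x: np.ndarray, y: np.ndarray, config: MetricConfig | None = None,
         mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE) in dB.

    Identical images have zero MSE; +inf is returned as the sentinel.
    """
    config = config or MetricConfig()
    err = mse(x, y, mask)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(config.data_range**2 / err))


def _ssim_components(mx, my, vx, vy, cov, constants, exponents):
    c1, c2, c3 = constants
    a, b, g = exponents
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    lum = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
    con = (2 * sx * sy + c2) / (vx + vy + c2)
    stru = (cov + c3) / (sx * sy + c3)
    return np.sign(lum) * np.abs(lum) ** a * np.sign(con) * np.abs(con) ** b * np.sign(stru) * np.abs(stru) ** g


def ssim(x: np.ndarray, y: np.ndarray, config: MetricConfig | None = None,
         mask: np.ndarray | None = None) -> float:
    """Structural similarity: product of luminance, contrast and structure terms.

    ``global`` mode uses whole-image (or mask-interior) statistics;
    ``windowed`` mode averages the per-window SSIM over every
    ``window_size`` x ``window_size`` window that fits inside the slice.
    The two agree exactly when the window equals the whole slice.
    """
    config = config or MetricConfig()
    x, y, mask = _validated_pair(x, y, mask)
    constants, exponents = config.constants, config.ssim_exponents
    if config.ssim_mode == "global" or mask is not None:
        xv = x[mask] if mask is not None else x.ravel()
        yv = y[mask] if mask is not None else y.ravel()
        cov = float(np.mean((xv - xv.mean()) * (yv - yv.mean())))
        return float(
            _ssim_components(xv.mean(), yv.mean(), xv.var(), yv.var(), cov, constants, exponents)
        )
    k = config.window_size
    if x.ndim != 2 or k > min(x.shape):
        raise ContractError("windowed SSIM needs a 2-D slice at least window_size wide")
    xw = np.lib.stride_tricks.sliding_window_view(x, (k, k)).reshape(-1, k * k)
    yw = np.lib.stride_tricks.sliding_window_view(y, (k, k)).reshape(-1, k * k)
    mx, my = xw.mean(axis=1), yw.mean(axis=1)
    vx, vy = xw.var(axis=1), yw.var(axis=1)
    cov = ((xw - mx[:, None]) * (yw - my[:, None])).mean(axis=1)
    return float(np.mean(_ssim_components(mx, my, vx, vy, cov, constants, exponents)))


def image_histogram(
    x: np.ndarray, config: MetricConfig | None = None, mask: np.ndarray | None = None
) -> HistogramDistribution:
    """Equal-width histogram over ``hist_range``, normalized to sum 1.

    Values outside the range are clipped into the edge bins so that every
    pixel contributes.  No epsilon floor is applied here; flooring happens
    only inside the KL computation.
    """
    config = config or MetricConfig()
    x = np.asarray(x, dtype=float)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise DegenerateInputError("mask selects no pixels")
        x = x[mask]
    elif config.exclude_background:
        # background sits at the bottom of the normalized range; without an
        # explicit brain mask, drop exactly-minimum pixels so the dominant
        # background bin does not drown the tissue distribution
        kept = x[x > config.hist_range[0]]
        if kept.size == 0:
            raise DegenerateInputError("image is entirely background")
        x = kept
    lo, hi = config.hist_range
    counts, edges = np.histogram(np.clip(x, lo, hi), bins=config.hist_bins, range=(lo, hi))
    return HistogramDistribution(edges, counts / counts.sum())


def hist_kl(
    x: np.ndarray,
    y: np.ndarray,
    config: MetricConfig | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Hist-KL: KL(P || Q) between the intensity histograms of the real image
    ``x`` (P) and the generated image ``y`` (Q), in nats.

    Both histograms are epsilon-floored and renormalized, so the divergence
    is finite and nonnegative; it is zero iff the histograms coincide.  Low
    Hist-KL indicates a high degree of intensity-distribution similarity.
    """
    config = config or MetricConfig()
    p = image_histogram(x, config, mask).probabilities
    q = image_histogram(y, config, mask).probabilities
    eps = config.hist_epsilon
    p = (p + eps) / (p + eps).sum()
    q = (q + eps) / (q + eps).sum()
    return float(np.sum(p * np.log(p / q)))


def frechet_distance(
    mu1: np.ndarray, cov1: np.ndarray, mu2: np.ndarray, cov2: np.ndarray
) -> float:
    """Fréchet distance between two Gaussians:
    ||mu1 - mu2||^2 + tr(cov1 + cov2 - 2 (cov1 cov2)^{1/2}).

    Symmetric in its arguments and >= 0 up to numerical tolerance.  A
    near-singular covariance product is stabilized by a small diagonal
    jitter (with a warning).
    """
    mu1 = np.asarray(mu1, dtype=float).ravel()
    mu2 = np.asarray(mu2, dtype=float).ravel()
    cov1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    cov2 = np.atleast_2d(np.asarray(cov2, dtype=float))
    if mu1.shape != mu2.shape or cov1.shape != cov2.shape or cov1.shape[0] != mu1.size:
        raise ContractError("mean/covariance dimensions do not match")
    diff = mu1 - mu2
    covmean = scipy.linalg.sqrtm(cov1 @ cov2)
    if not np.isfinite(covmean).all():
        warnings.warn("covariance product nearly singular; adding diagonal jitter")
        jitter = 1e-6 * np.eye(cov1.shape[0])
        covmean = scipy.linalg.sqrtm((cov1 + jitter) @ (cov2 + jitter))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    fd = float(diff @ diff + np.trace(cov1) + np.trace(cov2) - 2.0 * np.trace(covmean))
    return max(fd, 0.0) if abs(fd) < 1e-8 else fd


def metric_report(
    x: np.ndarray,
    y: np.ndarray,
    config: MetricConfig | None = None,
    mask: np.ndarray | None = None,
    region_label: str | None = None,
    slice_index: int | None = None,
) -> MetricReport:
    """All four metrics for one real/generated pair."""
    config = config or MetricConfig()
    return MetricReport(
        psnr_db=psnr(x, y, config, mask),
        ssim=ssim(x, y, config, mask),
        mse=mse(x, y, mask),
        hist_kl=hist_kl(x, y, config, mask),
        region_label=region_label,
        slice_index=slice_index,
    )
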