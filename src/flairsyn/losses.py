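"""GAN objectives: least-squares adversarial, cycle-consistency, conditional
BCE + L1, and the autoencoder reconstruction loss.

The public functions return scalar loss values on numpy arrays of patch
scores / image slices.  The ``*_grad`` helpers additionally return analytic
gradients and are what the training loops consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractError

__all__ = [
    "LossConfig",
    "lsgan_discriminator_loss",
    "lsgan_generator_loss",
    "cycle_consistency_loss",
    "cyclegan_objective",
    "pix2pix_generator_loss",
    "pix2pix_discriminator_loss",
    "reconstruction_mse_loss",
    "bce_with_logits_grad",
    "lsgan_generator_loss_grad",
    "lsgan_discriminator_loss_grad",
    "mae_grad",
    "mse_grad",
]

_P_MIN = 1e-7


@dataclass
class LossConfig:
    """Weights and options for every loss term.

    ``label_smoothing`` is the amount subtracted from the hard real label,
    so the discriminator's real-label target is ``1 - label_smoothing``
    (one-sided smoothing).  ``lambda_l1 = 100`` weights the L1 term of the
    pix2pix generator objective; ``lambda_cycle = 10`` weights the
    cycle-consistency term of the CycleGAN objective.
    """

    lambda_cycle: float = 10.0
    lambda_l1: float = 100.0
    label_smoothing: float = 0.0
    adversarial_form: str = "least_squares"  # or "binary_cross_entropy"

    def __post_init__(self):
        if self.lambda_cycle < 0 or self.lambda_l1 < 0:
            raise ValueError("loss weights must be nonnegative")
        if not 0 < self.real_target <= 1:
            raise ValueError("real-label target must lie in (0, 1]")
        if self.adversarial_form not in ("least_squares", "binary_cross_entropy"):
            raise ValueError(f"unknown adversarial_form {self.adversarial_form!r}")

    @property
    def real_target(self) -> float:
        return 1.0 - self.label_smoothing


def _check_same_shape(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if np.shape(a) != np.shape(b):
        raise ContractError(f"{what}: shape mismatch {np.shape(a)} vs {np.shape(b)}")


# ---------------------------------------------------------------------------
# least-squares adversarial losses (CycleGAN)
# ---------------------------------------------------------------------------

def lsgan_discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray, real_target: float = 1.0) -> float:
    """Mean (D(real) - target)^2 + mean D(fake)^2 over patch scores."""
    _check_same_shape(d_real, d_fake, "lsgan_discriminator_loss")
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    return float(np.mean((d_real - real_target) ** 2) + np.mean(d_fake**2))


def lsgan_generator_loss(d_fake: np.ndarray) -> float:
    """Mean (D(fake) - 1)^2: the generator tries to make fakes score as real."""
    return float(np.mean((np.asarray(d_fake, dtype=float) - 1.0) ** 2))


def lsgan_generator_loss_grad(d_fake: np.ndarray) -> tuple[float, np.ndarray]:
    d_fake = np.asarray(d_fake, dtype=float)
    loss = float(np.mean((d_fake - 1.0) ** 2))
    return loss, 2.0 * (d_fake - 1.0) / d_fake.size


def lsgan_discriminator_loss_grad(
    d_real: np.ndarray, d_fake: np.ndarray, real_target: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    _check_same_shape(d_real, d_fake, "lsgan_discriminator_loss")
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    loss = float(np.mean((d_real - real_target) ** 2) + np.mean(d_fake**2))
    return loss, 2.0 * (d_real - real_target) / d_real.size, 2.0 * d_fake / d_fake.size


# ---------------------------------------------------------------------------
# cycle consistency
# ---------------------------------------------------------------------------

def cycle_consistency_loss(
    x: np.ndarray, x_cycled: np.ndarray, y: np.ndarray, y_cycled: np.ndarray
) -> float:
    """Mean |F(G(x)) - x| + mean |G(F(y)) - y| (both directions of the cycle)."""
    _check_same_shape(x, x_cycled, "cycle_consistency_loss (x)")
    _check_same_shape(y, y_cycled, "cycle_consistency_loss (y)")
    x, x_cycled = np.asarray(x, dtype=float), np.asarray(x_cycled, dtype=float)
    y, y_cycled = np.asarray(y, dtype=float), np.asarray(y_cycled, dtype=float)
    return float(np.mean(np.abs(x_cycled - x)) + np.mean(np.abs(y_cycled - y)))


def cyclegan_objective(adv_G: float, adv_F: float, cyc: float, config: LossConfig) -> float:
    """Total objective: two adversarial terms plus lambda_cycle times the cyclic term."""
    return float(adv_G + adv_F + config.lambda_cycle * cyc)


# ---------------------------------------------------------------------------
# pix2pix (BCE + L1)
# ---------------------------------------------------------------------------

def _bce(p: np.ndarray, target: float) -> float:
    p = np.clip(np.asarray(p, dtype=float), _P_MIN, 1.0 - _P_MIN)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def _as_probabilities(scores: np.ndarray, from_logits: bool) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if from_logits:
        return 1.0 / (1.0 + np.exp(-scores))
    if np.any(scores < 0.0) or np.any(scores > 1.0):
        raise ContractError("patch scores outside [0, 1]; pass from_logits=True for raw scores")
    return scores


def pix2pix_generator_loss(
    d_fake: np.ndarray,
    y: np.ndarray,
    y_hat: np.ndarray,
    config: LossConfig,
    from_logits: bool = False,
) -> float:
    """BCE of the discriminator's fake scores against the real label, plus
    lambda_l1 times the mean absolute error between target and generation."""
    _check_same_shape(y, y_hat, "pix2pix_generator_loss")
    p_fake = _as_probabilities(d_fake, from_logits)
    mae = float(np.mean(np.abs(np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float))))
    return _bce(p_fake, 1.0) + config.lambda_l1 * mae


def pix2pix_discriminator_loss(
    d_real: np.ndarray,
    d_fake: np.ndarray,
    config: LossConfig,
    from_logits: bool = False,
) -> float:
    """BCE of real scores against the (possibly smoothed) real label plus
    BCE of fake scores against the fake label."""
    _check_same_shape(d_real, d_fake, "pix2pix_discriminator_loss")
    p_real = _as_probabilities(d_real, from_logits)
    p_fake = _as_probabilities(d_fake, from_logits)
    return _bce(p_real, config.real_target) + _bce(p_fake, 0.0)


def reconstruction_mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared reconstruction error (the autoencoder training loss)."""
    _check_same_shape(y, y_hat, "reconstruction_mse_loss")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.mean((y - y_hat) ** 2))


# ---------------------------------------------------------------------------
# gradient helpers for the training loops
# ---------------------------------------------------------------------------

def bce_with_logits_grad(scores: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Numerically stable BCE on raw scores; returns (loss, dloss/dscores)."""
    s = np.asarray(scores, dtype=float)
    # log(1 + exp(-|s|)) formulation avoids overflow
    loss = float(np.mean(np.maximum(s, 0.0) - s * target + np.log1p(np.exp(-np.abs(s)))))
    p = 1.0 / (1.0 + np.exp(-s))
    return loss, (p - target) / s.size


def mae_grad(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``y_hat``."""
    diff = np.asarray(y_hat, dtype=float) - np.asarray(y, dtype=float)
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def mse_grad(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``y_hat``."""
    diff = np.asarray(y_hat, dtype=float) - np.asarray(y, dtype=float)
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
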