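"""Scikit-learn style estimators for the four translation model families.

Each estimator wraps the functional training core: ``fit(X, y)`` takes
source slices ``X`` and target slices ``y`` as ``(n_slices, H, W)`` arrays
normalized to [-1, 1], ``predict(X)`` returns generated target slices,
and fitted state lives in trailing-underscore attributes
(``generator_``, ``training_state_``, ``best_epoch_`` ...).  Estimators
compose with sklearn model selection; ``score`` reports mean SSIM.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError
from .losses import LossConfig
from .metrics import MetricConfig, ssim
from .networks import build_model_bundle
from .training import TrainConfig, TrainingData, predict_slices, train

__all__ = [
    "Pix2PixTranslator",
    "CycleGANTranslator",
    "AutoencoderTranslator",
]


def _check_slices(X, name="X"):
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ConfigurationError(f"{name} must be (n_slices, rows, cols), got shape {X.shape}")
    if len(X) == 0:
        raise ConfigurationError(f"{name} holds no slices")
    return X


class _BaseTranslator(BaseEstimator):
    """Shared fit/predict machinery; subclasses define the model family."""

    _family: str = ""

    def _loss_config(self) -> LossConfig:
        return LossConfig(
            lambda_cycle=getattr(self, "lambda_cycle", 10.0),
            lambda_l1=getattr(self, "lambda_l1", 100.0),
            label_smoothing=self.label_smoothing,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_generator=self.lr_generator,
            lr_discriminator=getattr(self, "lr_discriminator", self.lr_generator),
            seed=self.random_state,
            fid_every_epoch=self.fid_every_epoch,
        )

    def _build(self, image_shape):
        return build_model_bundle(
            self._family,
            image_shape,
            base_filters=self.base_filters,
            depth=getattr(self, "depth", None),
            n_resnet_blocks=getattr(self, "n_resnet_blocks", None),
            modified_discriminator=getattr(self, "modified_discriminator", None),
            noise_sd=getattr(self, "noise_sd", 0.1),
            seed=self.random_state,
        )

    def fit(self, X, y, fid_sources=None, validation=None):
        """Fit on paired (or unpaired) source/target slices.

        ``fid_sources`` — held-out source slices for per-epoch FID (needed
        when ``fid_every_epoch``); ``validation`` — optional ``(X_val,
        y_val)`` pair logged as a per-epoch validation loss.
        """
        X = _check_slices(X, "X")
        y = _check_slices(np.asarray(y), "y")
        if X.shape[1:] != y.shape[1:]:
            raise ConfigurationError("source and target slices must share spatial shape")
        paired = self._family != "cyclegan_unpaired"
        x_val, y_val = (validation if validation is not None else (None, None))
        data = TrainingData(
            x_train=X,
            y_train=y,
            x_val=x_val,
            y_val=y_val,
            fid_sources=fid_sources,
            paired=paired,
        )
        self.bundle_ = self._build(X.shape[1:])
        self.training_state_ = train(
            self.bundle_,
            data,
            loss_config=self._loss_config(),
            train_config=self._train_config(),
            embedder=self.embedder if self.fid_every_epoch else None,
            restore_best=self.restore_best_epoch,
        )
        self.generator_ = self.bundle_.generators[0]
        self.fid_history_ = list(self.training_state_.fid_history)
        self.best_epoch_ = self.training_state_.best_epoch
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X):
        """Generate target-modality slices from source slices."""
        if not hasattr(self, "generator_"):
            raise ConfigurationError("estimator is not fitted; call fit first")
        X = _check_slices(X, "X")
        return predict_slices(self.generator_, X)

    # translation is transform-shaped too
    transform = predict

    def score(self, X, y):
        """Mean SSIM between generations from X and targets y (higher is better)."""
        y = _check_slices(np.asarray(y), "y")
        pred = self.predict(X)
        cfg = MetricConfig()
        return float(np.mean([ssim(t, p, cfg) for t, p in zip(y, pred)]))


class Pix2PixTranslator(_BaseTranslator):
    """Paired translation: U-Net generator + conditional PatchGAN
    discriminator, BCE adversarial loss plus lambda_l1 * L1."""

    _family = "pix2pix"

    def __init__(
        self,
        base_filters=64,
        depth=None,
        epochs=100,
        batch_size=8,
        lr_generator=4e-4,
        lr_discriminator=1e-4,
        lambda_l1=100.0,
        label_smoothing=0.0,
        fid_every_epoch=False,
        embedder=None,
        restore_best_epoch=True,
        random_state=0,
    ):
        self.base_filters = base_filters
        self.depth = depth
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_generator = lr_generator
        self.lr_discriminator = lr_discriminator
        self.lambda_l1 = lambda_l1
        self.label_smoothing = label_smoothing
        self.fid_every_epoch = fid_every_epoch
        self.embedder = embedder
        self.restore_best_epoch = restore_best_epoch
        self.random_state = random_state

    @property
    def discriminator_(self):
        return self.bundle_.discriminators[0]


class CycleGANTranslator(_BaseTranslator):
    """Cycle-consistent translation with two ResNet generators and two
    PatchGAN discriminators (least-squares adversarial loss).

    ``paired=False`` trains on unpaired domains (source and target slices
    from disjoint subjects); the modified discriminators (spectral
    normalization + training-time Gaussian noise + label smoothing)
    mitigate mode collapse and are on by default.
    """

    def __init__(
        self,
        paired=True,
        base_filters=64,
        n_resnet_blocks=None,
        epochs=100,
        batch_size=1,
        lr_generator=4e-4,
        lr_discriminator=1e-4,
        lambda_cycle=10.0,
        label_smoothing=0.1,
        modified_discriminator=True,
        noise_sd=0.1,
        fid_every_epoch=False,
        embedder=None,
        restore_best_epoch=True,
        random_state=0,
    ):
        self.paired = paired
        self.base_filters = base_filters
        self.n_resnet_blocks = n_resnet_blocks
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_generator = lr_generator
        self.lr_discriminator = lr_discriminator
        self.lambda_cycle = lambda_cycle
        self.label_smoothing = label_smoothing
        self.modified_discriminator = modified_discriminator
        self.noise_sd = noise_sd
        self.fid_every_epoch = fid_every_epoch
        self.embedder = embedder
        self.restore_best_epoch = restore_best_epoch
        self.random_state = random_state

    @property
    def _family(self):
        return "cyclegan_paired" if self.paired else "cyclegan_unpaired"

    @property
    def inverse_generator_(self):
        """The target-to-source generator F."""
        return self.bundle_.generators[1]


class AutoencoderTranslator(_BaseTranslator):
    """The ablation: the pix2pix generator stack without skip connections,
    trained with plain MSE reconstruction loss and no discriminator."""

    _family = "autoencoder"

    def __init__(
        self,
        base_filters=64,
        depth=None,
        epochs=100,
        batch_size=8,
        lr_generator=4e-4,
        label_smoothing=0.0,
        fid_every_epoch=False,
        embedder=None,
        restore_best_epoch=True,
        random_state=0,
    ):
        self.base_filters = base_filters
        self.depth = depth
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_generator = lr_generator
        self.label_smoothing = label_smoothing
        self.fid_every_epoch = fid_every_epoch
        self.embedder = embedder
        self.restore_best_epoch = restore_best_epoch
        self.random_state = random_state
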