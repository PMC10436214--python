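"""Training loops for the four model families.

Common recipe: Adam optimizers with asymmetric initial learning rates
(4e-4 for generators, 1e-4 for discriminators), learning rate fixed for
the first half of training then decayed linearly to zero, 100 epochs,
batch size 8 for pix2pix/autoencoder and 1 for the CycleGANs.
Discriminator and generator alternate one update per step, discriminator
first.  With ``fid_every_epoch`` the Fréchet distance between embedded
real training targets and generations from a held-out source subset is
appended after every epoch, and the epoch with the lowest FID is selected
as the best model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .exceptions import ConfigurationError, ContractError
from .losses import (
    LossConfig,
    bce_with_logits_grad,
    cycle_consistency_loss,
    lsgan_discriminator_loss_grad,
    lsgan_generator_loss_grad,
    mae_grad,
    mse_grad,
)
from .networks import ModelBundle
from .nn import Adam, Module

__all__ = [
    "TrainConfig",
    "TrainingState",
    "TrainingData",
    "lr_schedule",
    "select_best_epoch",
    "compute_epoch_fid",
    "embedding_stats",
    "train",
    "predict_slices",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8  # pix2pix/autoencoder; CycleGANs use 1
    lr_generator: float = 4e-4
    lr_discriminator: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    seed: int = 0
    fid_every_epoch: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class TrainingData:
    """Array-level training inputs, already normalized to [-1, 1].

    For paired families ``x_train[i]`` and ``y_train[i]`` are co-registered
    slices of one subject.  For the unpaired CycleGAN the two arrays come
    from disjoint subject sets and need not be equally long.  ``fid_sources``
    are held-out source slices excluded from the gradient stream.
    """

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray | None = None
    y_val: np.ndarray | None = None
    fid_sources: np.ndarray | None = None
    paired: bool = True

    def __post_init__(self):
        if self.paired and len(self.x_train) != len(self.y_train):
            raise ConfigurationError("paired training requires matching x/y lengths")


@dataclass
class TrainingState:
    epoch: int = -1
    gen_losses: list[float] = field(default_factory=list)
    disc_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    fid_history: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    checkpoint_paths: list[str] = field(default_factory=list)


def lr_schedule(epoch: int, total_epochs: int, base_lr: float) -> float:
    """Constant for the first half of training, then linear decay to zero.

    ``lr(total_epochs) == 0`` exactly; the schedule is continuous at the
    halfway point.
    """
    if epoch < 0 or epoch > total_epochs:
        raise ContractError(f"epoch {epoch} outside [0, {total_epochs}]")
    half = total_epochs / 2.0
    if epoch <= half:
        return base_lr
    return base_lr * (total_epochs - epoch) / (total_epochs - half)


def select_best_epoch(fid_history) -> int:
    """Index of the lowest FID; ties resolve to the earliest epoch."""
    fid_history = list(fid_history)
    if not fid_history:
        raise ContractError("fid_history is empty")
    return int(np.argmin(fid_history))


def embedding_stats(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of an (n_samples, dim) feature set."""
    features = np.asarray(features, dtype=float)
    mu = features.mean(axis=0)
    cov = np.cov(features, rowvar=False)
    return mu, np.atleast_2d(cov)


def predict_slices(generator: Module, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Run a generator over (N, H, W) slices in evaluation mode."""
    x = np.asarray(x, dtype=float)
    was_training = generator.training
    generator.eval()
    outs = []
    for i in range(0, len(x), batch_size):
        out = generator.forward(x[i : i + batch_size, None])
        outs.append(out[:, 0])
    generator.clear_context()
    generator.train(was_training)
    return np.concatenate(outs, axis=0)


def compute_epoch_fid(
    generator: Module,
    fid_sources: np.ndarray,
    real_targets: np.ndarray | None,
    embedder: Callable[[np.ndarray], np.ndarray],
    real_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """FID-style Fréchet distance for one epoch.

    Generates target slices from the held-out sources, embeds generated and
    real sets with the injected embedder, fits a Gaussian to each and
    returns their Fréchet distance.  ``real_stats`` may carry precomputed
    real-set moments (the real set — all eligible training targets — does
    not change between epochs).
    """
    from .metrics import frechet_distance

    if len(fid_sources) == 0:
        raise ContractError("fid_sources must be nonempty")
    if real_stats is None:
        if real_targets is None:
            raise ContractError("either real_targets or real_stats is required")
        real_stats = embedding_stats(embedder(np.asarray(real_targets, dtype=float)))
    generated = predict_slices(generator, fid_sources)
    mu_g, cov_g = embedding_stats(embedder(generated))
    mu_r, cov_r = real_stats
    return frechet_distance(mu_r, cov_r, mu_g, cov_g)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: ModelBundle, path: str | Path) -> None:
    arrays = {}
    for mi, module in enumerate(bundle.modules()):
        for name, arr in module.state_arrays().items():
            arrays[f"m{mi}_{name}"] = arr
    np.savez(path, **arrays)


def load_checkpoint(bundle: ModelBundle, path: str | Path) -> None:
    with np.load(path) as data:
        for mi, module in enumerate(bundle.modules()):
            prefix = f"m{mi}_"
            state = {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            module.load_state_arrays(state)


def _snapshot(bundle: ModelBundle) -> list[np.ndarray]:
    return [p.value.copy() for m in bundle.modules() for p in m.parameters()]


def _restore(bundle: ModelBundle, snap: list[np.ndarray]) -> None:
    params = [p for m in bundle.modules() for p in m.parameters()]
    for p, v in zip(params, snap):
        p.value = v.copy()
        p.grad = np.zeros_like(p.value)


# ---------------------------------------------------------------------------
# the per-family training loops
# ---------------------------------------------------------------------------

def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _val_loss(generator: Module, x_val, y_val, kind: str) -> float:
    pred = predict_slices(generator, x_val)
    diff = pred - np.asarray(y_val, dtype=float)
    return float(np.mean(np.abs(diff)) if kind == "l1" else np.mean(diff**2))


def train(
    bundle: ModelBundle,
    data: TrainingData,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
    embedder: Callable[[np.ndarray], np.ndarray] | None = None,
    real_fid_targets: np.ndarray | None = None,
    checkpoint_dir: str | Path | None = None,
    restore_best: bool = True,
    callback: Callable[[int, TrainingState], None] | None = None,
) -> TrainingState:
    """Train one model bundle on slice arrays; returns the training state.

    With ``fid_every_epoch`` the per-epoch FID drives best-epoch selection
    and (``restore_best``) the bundle is left at the lowest-FID parameters.
    The loss trajectory is deterministic for a fixed seed on fixed data.
    """
    loss_config = loss_config or LossConfig()
    cfg = train_config or TrainConfig()
    family = bundle.family
    if family == "cyclegan_unpaired" and data.paired:
        raise ConfigurationError("cyclegan_unpaired requires unpaired TrainingData")
    if family in ("pix2pix", "autoencoder", "cyclegan_paired") and not data.paired:
        raise ConfigurationError(f"{family} requires paired TrainingData")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % 2**31, 17]))
    state = TrainingState()
    fid_on = cfg.fid_every_epoch
    if fid_on:
        if embedder is None or data.fid_sources is None:
            raise ConfigurationError("fid_every_epoch requires an embedder and fid_sources")
        reals = real_fid_targets if real_fid_targets is not None else data.y_train
        real_stats = embedding_stats(embedder(np.asarray(reals, dtype=float)))
    best_fid, best_snap = np.inf, None

    step_fns = {
        "pix2pix": _pix2pix_epoch,
        "autoencoder": _autoencoder_epoch,
        "cyclegan_paired": _cyclegan_epoch,
        "cyclegan_unpaired": _cyclegan_epoch,
    }
    opts = _make_optimizers(bundle, cfg)

    for epoch in range(cfg.epochs):
        for opt, base in opts:
            opt.lr = lr_schedule(epoch, cfg.epochs, base)
        gen_loss, disc_loss = step_fns[family](bundle, data, loss_config, cfg, opts, rng)
        state.epoch = epoch
        state.gen_losses.append(gen_loss)
        state.disc_losses.append(disc_loss)
        if data.x_val is not None and data.y_val is not None:
            kind = "mse" if family == "autoencoder" else "l1"
            state.val_losses.append(_val_loss(bundle.generators[0], data.x_val, data.y_val, kind))
        if fid_on:
            fid = compute_epoch_fid(
                bundle.generators[0], data.fid_sources, None, embedder, real_stats=real_stats
            )
            state.fid_history.append(fid)
            if fid < best_fid:
                best_fid, best_snap = fid, _snapshot(bundle)
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir) / f"epoch_{epoch:04d}.npz"
            save_checkpoint(bundle, path)
            state.checkpoint_paths.append(str(path))
        if callback is not None:
            callback(epoch, state)

    if fid_on:
        state.best_epoch = select_best_epoch(state.fid_history)
        if restore_best and best_snap is not None:
            _restore(bundle, best_snap)
    return state


def _make_optimizers(bundle: ModelBundle, cfg: TrainConfig):
    opts = []
    for g in bundle.generators:
        opts.append(
            (Adam(g.parameters(), cfg.lr_generator, cfg.adam_beta1, cfg.adam_beta2), cfg.lr_generator)
        )
    for d in bundle.discriminators:
        opts.append(
            (Adam(d.parameters(), cfg.lr_discriminator, cfg.adam_beta1, cfg.adam_beta2), cfg.lr_discriminator)
        )
    return opts


def _pix2pix_epoch(bundle, data, loss_config, cfg, opts, rng):
    G, D = bundle.generators[0], bundle.discriminators[0]
    (opt_g, _), (opt_d, _) = opts
    G.train(), D.train()
    gen_losses, disc_losses = [], []
    x_all = np.asarray(data.x_train, dtype=float)
    y_all = np.asarray(data.y_train, dtype=float)
    for idx in _epoch_batches(len(x_all), cfg.batch_size, rng):
        x = x_all[idx][:, None]
        y = y_all[idx][:, None]
        # discriminator update (conditional: scores concat(source, target))
        fake = G.forward(x)
        G.clear_context()
        D.zero_grad()
        s_real = D.forward(np.concatenate([x, y], axis=1))
        s_fake = D.forward(np.concatenate([x, fake], axis=1))
        l_real, g_real = bce_with_logits_grad(s_real, loss_config.real_target)
        l_fake, g_fake = bce_with_logits_grad(s_fake, 0.0)
        D.backward(g_fake)
        D.backward(g_real)
        opt_d.step()
        disc_losses.append(l_real + l_fake)
        # generator update
        G.zero_grad()
        D.zero_grad()
        fake = G.forward(x)
        s_fake = D.forward(np.concatenate([x, fake], axis=1))
        adv, g_s = bce_with_logits_grad(s_fake, 1.0)
        g_into_fake = D.backward(g_s)[:, 1:]
        l1, g_l1 = mae_grad(y, fake)
        G.backward(g_into_fake + loss_config.lambda_l1 * g_l1)
        opt_g.step()
        gen_losses.append(adv + loss_config.lambda_l1 * l1)
    return float(np.mean(gen_losses)), float(np.mean(disc_losses))


def _autoencoder_epoch(bundle, data, loss_config, cfg, opts, rng):
    G = bundle.generators[0]
    (opt_g, _), = opts
    G.train()
    losses = []
    x_all = np.asarray(data.x_train, dtype=float)
    y_all = np.asarray(data.y_train, dtype=float)
    for idx in _epoch_batches(len(x_all), cfg.batch_size, rng):
        x = x_all[idx][:, None]
        y = y_all[idx][:, None]
        G.zero_grad()
        y_hat = G.forward(x)
        loss, grad = mse_grad(y, y_hat)
        G.backward(grad)
        opt_g.step()
        losses.append(loss)
    return float(np.mean(losses)), 0.0


def _cyclegan_epoch(bundle, data, loss_config, cfg, opts, rng):
    G, F = bundle.generators  # G: X->Y, F: Y->X
    D_X, D_Y = bundle.discriminators
    (opt_g, _), (opt_f, _), (opt_dx, _), (opt_dy, _) = opts
    for mod in (G, F, D_X, D_Y):
        mod.train()
    rt = loss_config.real_target
    lam = loss_config.lambda_cycle
    gen_losses, disc_losses = [], []
    x_all = np.asarray(data.x_train, dtype=float)
    y_all = np.asarray(data.y_train, dtype=float)
    x_order = rng.permutation(len(x_all))
    y_order = x_order if data.paired else rng.permutation(len(y_all))
    n = len(x_order) if data.paired else min(len(x_order), len(y_order))
    for bi in range(0, n, cfg.batch_size):
        x = x_all[x_order[bi : bi + cfg.batch_size]][:, None]
        y = y_all[y_order[bi : bi + cfg.batch_size]][:, None]
        # discriminators first
        fake_y = G.forward(x)
        G.clear_context()
        fake_x = F.forward(y)
        F.clear_context()
        d_total = 0.0
        for D, opt, real, fake in ((D_Y, opt_dy, y, fake_y), (D_X, opt_dx, x, fake_x)):
            D.zero_grad()
            s_real = D.forward(real)
            s_fake = D.forward(fake)
            l_d, g_real, g_fake = lsgan_discriminator_loss_grad(s_real, s_fake, rt)
            D.backward(g_fake)
            D.backward(g_real)
            opt.step()
            d_total += l_d
        disc_losses.append(d_total)
        # generators: adversarial + cycle in both directions
        for mod in (G, F, D_X, D_Y):
            mod.zero_grad()
        fake_y = G.forward(x)      # G#1
        cyc_x = F.forward(fake_y)  # F#1
        fake_x = F.forward(y)      # F#2
        cyc_y = G.forward(fake_x)  # G#2
        s_y = D_Y.forward(fake_y)
        s_x = D_X.forward(fake_x)
        adv_g, g_sy = lsgan_generator_loss_grad(s_y)
        adv_f, g_sx = lsgan_generator_loss_grad(s_x)
        cyc = cycle_consistency_loss(x, cyc_x, y, cyc_y)
        _, g_cyc_x = mae_grad(x, cyc_x)
        _, g_cyc_y = mae_grad(y, cyc_y)
        g_fake_y = D_Y.backward(g_sy)
        g_fake_x = D_X.backward(g_sx)
        g_fake_x = g_fake_x + G.backward(lam * g_cyc_y)  # pops G#2
        F.backward(g_fake_x)                             # pops F#2
        g_fake_y = g_fake_y + F.backward(lam * g_cyc_x)  # pops F#1
        G.backward(g_fake_y)                             # pops G#1
        opt_g.step()
        opt_f.step()
        gen_losses.append(adv_g + adv_f + lam * cyc)
    return float(np.mean(gen_losses)), float(np.mean(disc_losses))
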