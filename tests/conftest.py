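"""Shared fixtures: desk-scale phantom cohorts and trained models.

Training fixtures are session-scoped so the expensive fits run once and
are shared between the unit tests and the end-to-end checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from flairsyn.estimators import AutoencoderTranslator, Pix2PixTranslator
from flairsyn.metrics import MetricConfig, ssim
from flairsyn.networks import build_model_bundle
from flairsyn.phantoms import PhantomParams, generate_cohort
from flairsyn.preprocessing import normalize_intensity, select_slices
from flairsyn.training import predict_slices


@pytest.fixture(scope="session")
def phantom_params():
    """Noiseless desk-scale cohort: the translation is exactly learnable."""
    return PhantomParams(grid_shape=(32, 32, 12), n_subjects=6, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def cohort(phantom_params):
    return generate_cohort(phantom_params)


def _paired_slices(subject, target="fa"):
    idx = select_slices(subject.source_volume)
    x = normalize_intensity(subject.source_volume)
    y = normalize_intensity(subject.target_fa if target == "fa" else subject.target_md)
    return [x[:, :, z] for z in idx], [y[:, :, z] for z in idx]


@pytest.fixture(scope="session")
def slice_bank(cohort):
    """40 paired training slices from five subjects, test slices from the sixth."""
    xs, ys = [], []
    for subj in cohort[:5]:
        a, b = _paired_slices(subj)
        xs += a
        ys += b
    xt, yt = _paired_slices(cohort[5])
    return {
        "x_train": np.asarray(xs)[:40],
        "y_train": np.asarray(ys)[:40],
        "x_test": np.asarray(xt)[:10],
        "y_test": np.asarray(yt)[:10],
    }


def mean_ssim(targets, preds):
    cfg = MetricConfig()
    return float(np.mean([ssim(t, p, cfg) for t, p in zip(targets, preds)]))


@pytest.fixture(scope="session")
def recovery_runs(slice_bank):
    """Pix2pix vs untrained init vs identically-trained autoencoder, 3 seeds.

    Held-out SSIM of each, on the noiseless phantom translation task
    (40 training slices, 20 epochs, batch 8, lr 4e-4 / 1e-4, 32x32).
    """
    out = []
    X, Y = slice_bank["x_train"], slice_bank["y_train"]
    Xt, Yt = slice_bank["x_test"], slice_bank["y_test"]
    for seed in (0, 1, 2):
        untrained = build_model_bundle("pix2pix", X.shape[1:], base_filters=16, seed=seed)
        ssim_untrained = mean_ssim(Yt, predict_slices(untrained.generators[0], Xt))
        p2p = Pix2PixTranslator(base_filters=16, epochs=20, random_state=seed)
        p2p.fit(X, Y, validation=(Xt, Yt))
        ssim_p2p = mean_ssim(Yt, p2p.predict(Xt))
        ae = AutoencoderTranslator(base_filters=16, epochs=20, random_state=seed)
        ae.fit(X, Y)
        ssim_ae = mean_ssim(Yt, ae.predict(Xt))
        out.append(
            {
                "seed": seed,
                "ssim_untrained": ssim_untrained,
                "ssim_pix2pix": ssim_p2p,
                "ssim_autoencoder": ssim_ae,
                "pix2pix_val_losses": list(p2p.training_state_.val_losses),
            }
        )
    return out
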