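"""Training machinery: schedule, FID epoch selection, determinism,
checkpoint-reload equivalence and learning progress on noiseless phantoms."""

import itertools

import numpy as np
import pytest

from flairsyn.embedders import RandomConvEmbedder
from flairsyn.exceptions import ConfigurationError, ContractError
from flairsyn.losses import LossConfig
from flairsyn.networks import build_model_bundle
from flairsyn.phantoms import apply_mapping
from flairsyn.training import (
    TrainConfig,
    TrainingData,
    compute_epoch_fid,
    load_checkpoint,
    lr_schedule,
    predict_slices,
    save_checkpoint,
    select_best_epoch,
    train,
)


class TestLRSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 4e-4), (25, 4e-4), (50, 4e-4), (75, 2e-4), (100, 0.0),
    ])
    def test_paper_schedule_values(self, epoch, expected):
        assert lr_schedule(epoch, 100, 4e-4) == pytest.approx(expected, abs=1e-18)

    def test_non_increasing_and_continuous_at_half(self):
        vals = [lr_schedule(e, 100, 4e-4) for e in range(101)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert lr_schedule(50, 100, 4e-4) == pytest.approx(lr_schedule(51, 100, 4e-4), rel=0.03)

    def test_epoch_out_of_range(self):
        with pytest.raises(ContractError):
            lr_schedule(101, 100, 4e-4)


class TestBestEpoch:
    def test_argmin(self):
        assert select_best_epoch([5.0, 3.0, 4.0]) == 1

    def test_tie_earliest(self):
        assert select_best_epoch([2.0, 2.0]) == 0

    def test_all_permutations_of_four(self):
        values = [1.0, 2.0, 2.0, 3.0]
        for perm in itertools.permutations(values):
            k = select_best_epoch(list(perm))
            assert perm[k] == min(values)
            assert all(perm[j] > perm[k] for j in range(k))  # earliest tie

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            select_best_epoch([])


class TestEpochFID:
    def test_exact_mapping_generator_near_zero(self):
        """A 'generator' realizing the exact ground-truth mapping, compared
        against its own outputs as the real set, scores FID ~ 0."""

        class ExactMapper:
            training = False

            def forward(self, x):
                return apply_mapping((x[:, 0] + 1) / 2, "fa-like")[:, None] * 2 - 1

            def eval(self):
                return self

            def train(self, flag=True):
                return self

            def clear_context(self):
                pass

        rng = np.random.default_rng(0)
        sources = rng.uniform(0, 1, size=(32, 16, 16)) * 2 - 1
        mapper = ExactMapper()
        reals = mapper.forward(sources[:, None])[:, 0]
        emb = RandomConvEmbedder(channels=(4, 8), seed=0)
        fid = compute_epoch_fid(mapper, sources, reals, emb)
        assert fid == pytest.approx(0.0, abs=1e-6)

    def test_constant_generator_scores_worse(self):
        class ConstantGen:
            training = False

            def forward(self, x):
                return np.zeros_like(x)

            def eval(self):
                return self

            def train(self, flag=True):
                return self

            def clear_context(self):
                pass

        class Identity(ConstantGen):
            def forward(self, x):
                return x

        rng = np.random.default_rng(1)
        sources = rng.uniform(-1, 1, size=(48, 16, 16))
        emb = RandomConvEmbedder(channels=(4, 8), seed=0)
        fid_exact = compute_epoch_fid(Identity(), sources, sources, emb)
        fid_const = compute_epoch_fid(ConstantGen(), sources, sources, emb)
        assert fid_const > fid_exact

    def test_empty_sources_rejected(self):
        with pytest.raises(ContractError):
            compute_epoch_fid(None, np.empty((0, 8, 8)), None, lambda x: x)


def _tiny_data(n=16, size=16, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.05, 1.0, size=(n, size, size))
    y = apply_mapping(x, "fa-like")
    return TrainingData(x_train=x * 2 - 1, y_train=y * 2 - 1)


class TestTrainLoop:
    def test_family_split_compatibility(self):
        bundle = build_model_bundle("cyclegan_unpaired", (16, 16), base_filters=4,
                                    n_resnet_blocks=2, seed=0)
        with pytest.raises(ConfigurationError):
            train(bundle, _tiny_data(), TrainConfig(epochs=1))

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(epochs=0)

    def test_fixed_seed_reproduces_epoch1_loss(self):
        data = _tiny_data()
        losses = []
        for _ in range(2):
            bundle = build_model_bundle("pix2pix", (16, 16), base_filters=4, seed=3)
            cfg = TrainConfig(epochs=1, batch_size=8, seed=3)
            state = train(bundle, data, LossConfig(), cfg)
            losses.append(state.gen_losses[0])
        assert losses[0] == losses[1]

    def test_checkpoint_reload_reproduces_val_loss(self, tmp_path):
        """Reloading the epoch-k checkpoint reproduces the logged epoch-k
        validation loss on the same fixed batch."""
        data = _tiny_data()
        data.x_val, data.y_val = data.x_train[:4], data.y_train[:4]
        bundle = build_model_bundle("pix2pix", (16, 16), base_filters=4, seed=1)
        cfg = TrainConfig(epochs=3, batch_size=8, seed=1)
        state = train(bundle, data, LossConfig(), cfg, checkpoint_dir=tmp_path)
        assert len(state.checkpoint_paths) == 3
        k = 1
        fresh = build_model_bundle("pix2pix", (16, 16), base_filters=4, seed=99)
        load_checkpoint(fresh, state.checkpoint_paths[k])
        pred = predict_slices(fresh.generators[0], data.x_val)
        val = float(np.mean(np.abs(pred - data.y_val)))
        assert val == pytest.approx(state.val_losses[k], rel=1e-12)

    def test_checkpoint_roundtrip_identical_params(self, tmp_path):
        bundle = build_model_bundle("cyclegan_paired", (16, 16), base_filters=4,
                                    n_resnet_blocks=2, seed=5)
        path = tmp_path / "ck.npz"
        save_checkpoint(bundle, path)
        other = build_model_bundle("cyclegan_paired", (16, 16), base_filters=4,
                                   n_resnet_blocks=2, seed=6)
        load_checkpoint(other, path)
        for m1, m2 in zip(bundle.modules(), other.modules()):
            for p1, p2 in zip(m1.parameters(), m2.parameters()):
                assert np.array_equal(p1.value, p2.value)

    def test_fid_history_and_best_epoch(self):
        data = _tiny_data()
        data.fid_sources = data.x_train[:6]
        bundle = build_model_bundle("pix2pix", (16, 16), base_filters=4, seed=0)
        cfg = TrainConfig(epochs=3, batch_size=8, seed=0, fid_every_epoch=True)
        emb = RandomConvEmbedder(channels=(4, 8), seed=0)
        state = train(bundle, data, LossConfig(), cfg, embedder=emb)
        assert len(state.fid_history) == 3
        assert state.best_epoch == int(np.argmin(state.fid_history))


class TestLearningProgress:
    def test_trained_beats_untrained_on_holdout(self, recovery_runs):
        for run in recovery_runs:
            assert run["ssim_pix2pix"] > run["ssim_untrained"]

    def test_smoothed_validation_l1_decreases_in_first_half(self, recovery_runs):
        """5-epoch moving average of held-out L1 drops over the first half
        of training on the noiseless phantom task."""
        improved = 0
        for run in recovery_runs:
            val = np.asarray(run["pix2pix_val_losses"])
            smooth = np.convolve(val, np.ones(5) / 5, mode="valid")
            if smooth[len(val) // 2 - 2] < smooth[0]:
                improved += 1
        assert improved >= 2
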