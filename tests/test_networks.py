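"""Architecture contracts: shapes, boundedness, parameter audits,
receptive fields and the modified-discriminator behaviour."""

import numpy as np
import pytest

from flairsyn.exceptions import ConfigurationError
from flairsyn.networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    ModelBundle,
    ResnetBlock,
    build_autoencoder,
    build_model_bundle,
    build_patchgan_discriminator,
    build_resnet_generator,
    build_unet_generator,
)
from flairsyn.nn import Conv2d, SpectralNormConv2d

rng = np.random.default_rng(0)


def _spec(shape=(64, 64, 1), **kw):
    return GeneratorSpec(input_shape=shape, base_filters=kw.pop("base_filters", 4), **kw)


class TestGenerators:
    @pytest.mark.parametrize("builder,family,kw", [
        (build_unet_generator, "unet", {}),
        (build_resnet_generator, "resnet", {"n_resnet_blocks": 2}),
        (build_autoencoder, "unet", {"skip_connections": False}),
    ], ids=["unet", "resnet", "autoencoder"])
    def test_shape_preserving_and_bounded(self, builder, family, kw):
        gen = builder(_spec(family=family, **kw), rng=np.random.default_rng(1))
        x = rng.normal(size=(2, 1, 64, 64))
        y = gen.forward(x)
        gen.clear_context()
        assert y.shape == x.shape
        assert np.isfinite(y).all() and np.abs(y).max() <= 1.0

    def test_zero_input_finite_bounded(self):
        gen = build_unet_generator(_spec(), rng=np.random.default_rng(1))
        y = gen.forward(np.zeros((1, 1, 64, 64)))
        gen.clear_context()
        assert np.isfinite(y).all() and np.abs(y).max() <= 1.0

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ConfigurationError):
            build_unet_generator(_spec(shape=(48, 48, 1), depth=5))

    def test_resnet_zero_branch_is_identity_flow(self):
        """Zeroing the transform branch makes each residual block an identity."""
        block = ResnetBlock(3, rng=np.random.default_rng(2))
        for p in block.parameters():
            p.value[...] = 0.0
        x = rng.normal(size=(1, 3, 8, 8))
        out = block.forward(x)
        block.clear_context()
        assert np.allclose(out, x)

    def test_resnet_block_receptive_field_is_5x5(self):
        """Impulse through the block's two stacked 3x3 convolutions spreads
        to exactly a 5x5 support."""
        block = ResnetBlock(1, rng=np.random.default_rng(3))
        convs = [l for l in block.branch.layers if isinstance(l, Conv2d)]
        assert len(convs) == 2
        impulse = np.zeros((1, 1, 11, 11))
        impulse[0, 0, 5, 5] = 1.0
        out = convs[1].forward(convs[0].forward(impulse))
        for c in convs:
            c.clear_context()
        # remove the bias floor so only the impulse response remains
        bias_out = convs[1].forward(convs[0].forward(np.zeros_like(impulse)))
        for c in convs:
            c.clear_context()
        support = np.abs(out - bias_out)[0, 0] > 1e-12
        ys, xs = np.nonzero(support)
        assert ys.min() == 3 and ys.max() == 7 and xs.min() == 3 and xs.max() == 7

    def test_resnet_needs_positive_blocks(self):
        with pytest.raises(ConfigurationError):
            build_resnet_generator(_spec(family="resnet", n_resnet_blocks=0))


class TestAutoencoderAudit:
    def test_hidden_layer_count_matches_unet(self):
        unet = build_unet_generator(_spec(depth=4), rng=np.random.default_rng(1))
        ae = build_autoencoder(_spec(depth=4, skip_connections=False), rng=np.random.default_rng(1))
        count = lambda g: len(g.enc_blocks) + len(g.dec_blocks)
        assert count(unet) == count(ae)

    def test_bottleneck_shapes_identical(self):
        unet = build_unet_generator(_spec(depth=4), rng=np.random.default_rng(1))
        ae = build_autoencoder(_spec(depth=4, skip_connections=False), rng=np.random.default_rng(1))
        x = rng.normal(size=(1, 1, 64, 64))
        for gen in (unet, ae):
            h = x
            for blk in gen.enc_blocks:
                h = blk.forward(h)
            gen.clear_context()
            assert h.shape == (1, 4 * min(2**3, 8), 4, 4)

    def test_parameter_count_difference_is_exactly_skip_weights(self):
        """U-Net params = autoencoder params + the extra input-channel weights
        of each skip-concatenation convolution (layer-by-layer audit)."""
        bf, depth = 4, 4
        unet = build_unet_generator(_spec(depth=depth), rng=np.random.default_rng(1))
        ae = build_autoencoder(_spec(depth=depth, skip_connections=False), rng=np.random.default_rng(1))
        f = [bf * min(2 ** (i - 1), 8) for i in range(1, depth + 1)]
        expected_extra = 0
        for level in range(1, depth):  # decoder blocks receiving a skip
            out_ch = f[level - 2] if level >= 2 else bf
            expected_extra += f[level - 1] * out_ch * 3 * 3
        assert unet.n_parameters() - ae.n_parameters() == expected_extra


class TestPatchGAN:
    def test_patch_grid_contract(self):
        disc = build_patchgan_discriminator(
            DiscriminatorSpec(input_shape=(64, 64, 1), base_filters=4)
        )
        y = disc.forward(rng.normal(size=(1, 1, 64, 64)))
        disc.clear_context()
        n_cells = y.shape[2] * y.shape[3]
        assert y.shape[:2] == (1, 1) and 1 < n_cells < 64 * 64

    def test_modified_eval_mode_deterministic(self):
        disc = build_patchgan_discriminator(
            DiscriminatorSpec(input_shape=(32, 32, 1), base_filters=4, modified=True, noise_sd=0.2),
            rng=np.random.default_rng(4),
        )
        x = rng.normal(size=(1, 1, 32, 32))
        disc.eval()
        a = disc.forward(x)
        disc.clear_context()
        b = disc.forward(x)
        disc.clear_context()
        assert np.array_equal(a, b)

    def test_modified_training_mode_is_stochastic(self):
        disc = build_patchgan_discriminator(
            DiscriminatorSpec(input_shape=(32, 32, 1), base_filters=4, modified=True, noise_sd=0.2),
            rng=np.random.default_rng(4),
        )
        x = rng.normal(size=(1, 1, 32, 32))
        disc.train()
        a = disc.forward(x)
        disc.clear_context()
        b = disc.forward(x)
        disc.clear_context()
        assert np.var(a - b) > 0

    def test_modified_weights_spectrally_normalized(self):
        """After power-iteration convergence every convolution's effective
        weight has largest singular value 1, checked by full SVD."""
        disc = build_patchgan_discriminator(
            DiscriminatorSpec(input_shape=(32, 32, 1), base_filters=4, modified=True, noise_sd=0.0),
            rng=np.random.default_rng(4),
        )
        x = rng.normal(size=(1, 1, 32, 32))
        for _ in range(100):
            disc.forward(x)
            disc.clear_context()
        sn_layers = [m for m in disc.modules() if isinstance(m, SpectralNormConv2d)]
        assert len(sn_layers) == 5  # every convolution wrapped
        for sn in sn_layers:
            w_eff = (sn.conv.weight.value * sn.conv.weight_scale).reshape(sn.conv.out_channels, -1)
            assert np.linalg.svd(w_eff, compute_uv=False)[0] == pytest.approx(1.0, abs=1e-3)


class TestModelBundle:
    @pytest.mark.parametrize("family,ng,nd", [
        ("pix2pix", 1, 1),
        ("cyclegan_paired", 2, 2),
        ("cyclegan_unpaired", 2, 2),
        ("autoencoder", 1, 0),
    ])
    def test_family_cardinalities(self, family, ng, nd):
        bundle = build_model_bundle(family, (32, 32), base_filters=4, n_resnet_blocks=2, seed=0)
        assert len(bundle.generators) == ng and len(bundle.discriminators) == nd

    def test_wrong_cardinality_rejected(self):
        gen = build_unet_generator(_spec(shape=(32, 32, 1)), rng=np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            ModelBundle("pix2pix", [gen], [])
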