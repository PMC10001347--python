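"""Conditioned GAN: geometry, losses, bookkeeping, training contracts."""

import numpy as np
import pytest

from dermforge import fixtures
from dermforge.gan import (
    EPS, GanBundle, GanConfig, build_discriminator, build_generator,
    discriminator_loss, generate_batch, generator_loss,
    interpolate_black_pixels, train_epoch, train_gan,
)


@pytest.fixture(scope="module")
def desk_bundle():
    return GanBundle.build(GanConfig.desk(32), seed=0)


@pytest.fixture(scope="module")
def desk_data():
    imgs = np.stack([
        fixtures.generate_lesion(fixtures.LesionSpec.random(c, i, size=32), 32)
        for c in range(6) for i in range(4)])
    labels = np.repeat(np.arange(6), 4)
    return imgs, labels


class TestGeneratorGeometry:
    def test_default_geometry(self):
        gen = build_generator()
        # latent+label concatenation carries base_filters + 1 = 129 channels
        assert gen.concat_channels == 129
        assert gen.label_embed_dim == 64
        assert gen.latent_dense.w.shape == (256, 128 * 8 * 8)  # 8192 nodes

    def test_output_shape_and_range(self):
        gen = build_generator()
        z = np.random.default_rng(0).standard_normal((2, 256))
        out = gen.generate(z, np.array([0, 5]))
        assert out.shape == (2, 128, 128, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            GanConfig(latent_dim=0)
        with pytest.raises(ValueError):
            GanConfig(image_size=100)


class TestDiscriminator:
    def test_conv_stack_sees_four_channels(self):
        disc = build_discriminator(image_size=32, base_filters=16)
        assert disc.downsample[0].w.shape[1] == 4  # RGB + label plane

    def test_dropout_rate(self):
        assert build_discriminator(image_size=32,
                                   base_filters=16).dropout.rate == 0.40

    def test_output_is_probability(self, desk_bundle, desk_data):
        imgs, labels = desk_data
        out = desk_bundle.discriminator.forward(
            np.transpose(imgs[:4], (0, 3, 1, 2)), labels[:4])
        assert out.shape == (4,)
        assert ((out.data > 0) & (out.data < 1)).all()

    def test_four_downsampling_stages_at_default_size(self):
        assert len(build_discriminator().downsample) == 4


class TestLosses:
    def test_closed_forms(self):
        assert generator_loss([0.5]) == pytest.approx(np.log(2), abs=1e-9)
        lr, lf = discriminator_loss([1 - EPS], [0.5])
        assert lr == pytest.approx(0.0, abs=1e-6)
        assert lf == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(20):
            d_real = rng.uniform(0.01, 0.99, size=8)
            d_fake = rng.uniform(0.01, 0.99, size=8)
            lr, lf = discriminator_loss(d_real, d_fake)
            oracle_r = -sum(np.log(p) for p in d_real) / len(d_real)
            oracle_f = -sum(np.log(1 - p) for p in d_fake) / len(d_fake)
            assert lr == pytest.approx(oracle_r, abs=1e-6)
            assert lf == pytest.approx(oracle_f, abs=1e-6)
            g = generator_loss(d_fake)
            oracle_g = -sum(np.log(p) for p in d_fake) / len(d_fake)
            assert g == pytest.approx(oracle_g, abs=1e-6)

    def test_saturated_probabilities_stay_finite(self):
        lr, lf = discriminator_loss([0.0, 1.0], [0.0, 1.0])
        assert np.isfinite([lr, lf, generator_loss([0.0])]).all()


class TestParamBookkeeping:
    def test_structural_identity(self, desk_bundle):
        rep = desk_bundle.param_report()
        assert rep["gan_total"] == rep["generator"] + 2 * rep["discriminator"]
        assert rep["gan_non_trainable"] == rep["discriminator"]
        assert rep["gan_trainable"] == rep["generator"] + rep["discriminator"]


class TestTraining:
    def test_generator_step_leaves_discriminator_frozen(self, desk_data):
        imgs, labels = desk_data
        bundle = GanBundle.build(GanConfig.desk(32), seed=3)
        bundle.opt_d.lr = 0.0  # silence D's own updates to isolate the G step
        d_before = [p.data.copy() for p in bundle.discriminator.parameters()]
        g_before = [p.data.copy() for p in bundle.generator.parameters()]
        train_epoch(bundle, imgs, labels, batch_size=8, rng=5)
        for before, p in zip(d_before, bundle.discriminator.parameters()):
            np.testing.assert_array_equal(before, p.data)
        assert any(not np.array_equal(b, p.data) for b, p in
                   zip(g_before, bundle.generator.parameters()))

    def test_epoch_record_fields(self, desk_data):
        imgs, labels = desk_data
        bundle = GanBundle.build(GanConfig.desk(32), seed=4)
        rec = train_epoch(bundle, imgs, labels, epoch=7, batch_size=8, rng=1)
        assert rec.epoch == 7
        assert np.isfinite([rec.g_loss, rec.d_loss_real, rec.d_loss_fake]).all()
        assert 0.0 <= rec.d_acc_real <= 1.0 and 0.0 <= rec.d_acc_fake <= 1.0

    def test_short_run_losses_finite(self, desk_data):
        imgs, labels = desk_data
        bundle = GanBundle.build(GanConfig.desk(32), seed=5)
        recs = train_gan(bundle, imgs, labels, epochs=5, batch_size=8, seed=2)
        assert len(recs) == 5
        assert np.isfinite([[r.g_loss, r.d_loss_real, r.d_loss_fake]
                            for r in recs]).all()

    def test_empty_source_rejected(self, desk_bundle):
        with pytest.raises(ValueError, match="empty"):
            train_epoch(desk_bundle, np.zeros((0, 32, 32, 3)),
                        np.zeros(0, dtype=int), batch_size=8, rng=0)

    def test_odd_batch_rejected(self, desk_bundle, desk_data):
        imgs, labels = desk_data
        with pytest.raises(ValueError, match="even"):
            train_epoch(desk_bundle, imgs, labels, batch_size=7, rng=0)


class TestGenerateBatch:
    def test_count_shape_and_determinism(self, desk_bundle):
        labels = [0, 1, 2, 3]
        a = generate_batch(desk_bundle, labels, rng_seed=9)
        b = generate_batch(desk_bundle, labels, rng_seed=9)
        assert a.shape == (4, 32, 32, 3)
        np.testing.assert_array_equal(a, b)

    def test_label_conditioning_pathway(self, desk_bundle):
        """Same noise, different labels -> different images (the label is
        wired through the embedding into the generator)."""
        a = generate_batch(desk_bundle, [3, 3], rng_seed=11)
        b = generate_batch(desk_bundle, [1, 1], rng_seed=11)
        assert not np.array_equal(a, b)

    def test_invalid_labels_rejected(self, desk_bundle):
        with pytest.raises(ValueError, match="labels"):
            generate_batch(desk_bundle, [0, 6], rng_seed=0)


class TestInterpolateBlackPixels:
    def test_noop_without_black_pixels(self):
        img = np.full((8, 8, 3), 0.5)
        np.testing.assert_array_equal(interpolate_black_pixels(img), img)

    def test_single_black_pixel_takes_neighbor_median(self):
        img = np.full((5, 5, 3), 0.5)
        img[2, 2] = 0.0
        out = interpolate_black_pixels(img)
        np.testing.assert_allclose(out[2, 2], 0.5)

    def test_mixed_channel_pixel_not_near_black(self):
        img = np.full((5, 5, 3), 0.5)
        img[2, 2] = [0.05, 0.5, 0.5]  # one channel low, not all
        out = interpolate_black_pixels(img)
        np.testing.assert_array_equal(out, img)

    def test_idempotent_and_preserves_bright_pixels(self, rng):
        img = rng.uniform(0.0, 1.0, size=(16, 16, 3))
        once = interpolate_black_pixels(img)
        np.testing.assert_array_equal(interpolate_black_pixels(once), once)
        bright = np.all(img > 0.1, axis=-1)
        np.testing.assert_array_equal(once[bright], img[bright])

    def test_fully_black_image_warns(self):
        img = np.zeros((4, 4, 3))
        with pytest.warns(UserWarning, match="black"):
            out = interpolate_black_pixels(img)
        np.testing.assert_array_equal(out, img)

    def test_black_cluster_fills_iteratively(self):
        img = np.full((7, 7, 3), 0.8)
        img[2:5, 2:5] = 0.0  # 3x3 hole: center has no valid neighbor at pass 1
        out = interpolate_black_pixels(img)
        assert (out > 0.1).all()
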