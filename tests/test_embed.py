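"""Contrastive pretraining: augmentation, loss formula, encoder training,
embedding."""
import numpy as np
import pytest

from pseudosorter.embed import (ContrastiveConfig, Encoder, EncoderSpec,
                                augment, embed_all, nnclr_loss, pretrain)

SMALL_SPEC = EncoderSpec(layer_dims=(63, 64, 64, 10), projection_width=10)


def brute_force_nnclr_loss(anchor, support, tau, positive_index=0):
    """Direct evaluation of -log exp(sim(a, s+)/tau) / sum_j exp(sim(a, s_j)/tau)."""
    import math
    a = np.asarray(anchor, float)
    a = a / np.linalg.norm(a)
    sims = []
    for s in np.atleast_2d(support):
        s = np.asarray(s, float)
        sims.append(float(a @ (s / np.linalg.norm(s))))
    num = math.exp(sims[positive_index] / tau)
    den = sum(math.exp(s / tau) for s in sims)
    return -math.log(num / den)


class TestAugment:
    def test_zero_level_is_identity(self, rng):
        x = rng.normal(size=(10, 63)).astype(np.float32)
        np.testing.assert_array_equal(augment(x, 0.0, rng), x)

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(10, 63)).astype(np.float32)
        a = augment(x, 0.075, np.random.default_rng(4))
        b = augment(x, 0.075, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)

    def test_noise_bounded_by_level_times_range(self, rng):
        x = rng.normal(size=(10_000, 63)).astype(np.float32)
        out = augment(x, 0.075, np.random.default_rng(1))
        noise = out - x
        ptp = x.max(axis=1) - x.min(axis=1)
        # empirical per-row std stays below the per-row cap (3 sigma slack)
        per_row_std = noise.std(axis=1)
        assert np.all(per_row_std <= 0.075 * ptp * (1 + 3 / np.sqrt(63)))

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((2, 3), np.float32), -0.1)


class TestNnclrLoss:
    def test_lone_positive_gives_zero(self):
        z = np.array([1.0, 0.0, 0.0])
        assert nnclr_loss(z, z[None, :], 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_distractor_closed_form(self):
        # sims 1 and 0 at tau 0.1: loss = log(1 + e^-10)
        anchor = np.array([1.0, 0.0])
        support = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert nnclr_loss(anchor, support, 0.1) == pytest.approx(
            np.log1p(np.exp(-10.0)), rel=1e-9)

    def test_scale_invariance(self, rng):
        anchor = rng.normal(size=6)
        support = rng.normal(size=(5, 6))
        a = nnclr_loss(anchor, support, 0.1)
        b = nnclr_loss(3.7 * anchor, 42.0 * support, 0.1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(50):
            m = rng.integers(2, 16)
            anchor = rng.normal(size=8)
            support = rng.normal(size=(m, 8))
            got = nnclr_loss(anchor, support, 0.1)
            want = brute_force_nnclr_loss(anchor, support, 0.1)
            assert abs(got - want) < 1e-6

    def test_zero_norm_embedding_rejected(self):
        with pytest.raises(ValueError):
            nnclr_loss(np.zeros(4), np.ones((2, 4)), 0.1)


class TestPretrain:
    def test_epoch_zero_returns_usable_random_encoder(self, two_class_set):
        wset, _ = two_class_set
        enc = pretrain(wset.features, SMALL_SPEC,
                       ContrastiveConfig(epochs=0, seed=0))
        z = embed_all(enc, wset.features)
        assert z.embeddings.shape == (len(wset), 10)

    def test_loss_decreases_on_two_class_set(self, two_class_set):
        wset, _ = two_class_set
        enc = pretrain(wset.features, SMALL_SPEC,
                       ContrastiveConfig(epochs=8, seed=0))
        assert enc.history[-1] < enc.history[0]

    def test_seeded_runs_reproduce_losses(self, two_class_set):
        wset, _ = two_class_set
        cfg = ContrastiveConfig(epochs=2, seed=3)
        a = pretrain(wset.features, SMALL_SPEC, cfg)
        b = pretrain(wset.features, SMALL_SPEC, cfg)
        assert a.history == b.history

    def test_feature_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pretrain(rng.normal(size=(300, 10)).astype(np.float32),
                     SMALL_SPEC, ContrastiveConfig(epochs=1, batch_size=64))


class TestEmbedAll:
    def test_empty_input(self):
        enc = Encoder(SMALL_SPEC, seed=0)
        out = embed_all(enc, np.empty((0, 63), np.float32))
        assert out.embeddings.shape == (0, 10)

    def test_duplicate_rows_embed_identically(self, rng):
        enc = Encoder(SMALL_SPEC, seed=0)
        row = rng.normal(size=63).astype(np.float32)
        z = embed_all(enc, np.stack([row, row])).embeddings
        np.testing.assert_array_equal(z[0], z[1])

    def test_dimensionality_always_ten(self, rng, two_class_set):
        wset, _ = two_class_set
        enc = Encoder(EncoderSpec(), seed=0)
        for n in (1, 7, 130):
            z = embed_all(enc, wset.features[:n])
            assert z.embeddings.shape == (n, 10)

    def test_classes_separate_after_pretraining(self, two_class_set):
        """Mean between-class latent distance exceeds mean within-class
        distance on a well-separated 2-class set."""
        wset, _ = two_class_set
        enc = pretrain(wset.features, SMALL_SPEC,
                       ContrastiveConfig(epochs=8, seed=0))
        z = embed_all(enc, wset.features).embeddings
        y = wset.labels
        a, b = z[y == 0][:300], z[y == 1][:300]
        within = np.linalg.norm(a[:, None] - a[None, :], axis=-1).mean()
        between = np.linalg.norm(a[:, None] - b[None, :], axis=-1).mean()
        assert between > within


class TestEncoderCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        enc = Encoder(SMALL_SPEC, seed=1)
        enc.fit_scaler(rng.normal(size=(100, 63)).astype(np.float32))
        path = str(tmp_path / "enc.npz")
        enc.save(path)
        loaded = Encoder.load(path)
        x = rng.normal(size=(5, 63)).astype(np.float32)
        np.testing.assert_array_equal(enc.embed(x), loaded.embed(x))
        assert loaded.fingerprint() == enc.fingerprint()
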