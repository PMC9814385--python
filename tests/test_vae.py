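"""Unit tests for the sequence VAE: shapes, loss closed forms, determinism,
memorization, persistence."""

import numpy as np
import pytest

from rxngen.corpus import CorpusSplit, Vocabulary, build_vocabulary, encode_equation
from rxngen.errors import ConfigurationError
from rxngen.vae import ModelConfig, ReactionVAE, kl_divergence, reparameterize


@pytest.fixture(scope="module")
def tiny_model():
    vocab = build_vocabulary(["C >> C", "O >> O", "[H][H] >> [H][H]"])
    cfg = ModelConfig(
        embedding_dim=12, latent_dim=8, hidden_dim=12, recurrent_dropout=0.2,
        kl_weight=0.1, learning_rate=1e-3, epochs=1, batch_size=2, seed=7,
    )
    return ReactionVAE(cfg, vocab), vocab


class TestConfig:
    def test_defaults_match_reference_settings(self):
        cfg = ModelConfig()
        assert cfg.embedding_dim == 500
        assert cfg.latent_dim == 350
        assert cfg.recurrent_dropout == 0.2
        assert cfg.kl_weight == 0.1
        assert cfg.learning_rate == 1e-5
        assert cfg.epochs == 500
        assert cfg.batch_size == 25
        assert cfg.hidden == 500  # hidden defaults to embedding_dim

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(embedding_dim=0),
            dict(recurrent_dropout=1.0),
            dict(kl_weight=-0.1),
            dict(batch_size=0),
            dict(recon_reduction="median"),
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelConfig(**kwargs)


class TestEncodeDecode:
    def test_encode_shapes_and_determinism(self, tiny_model):
        model, vocab = tiny_model
        codes = encode_equation("C >> C", vocab).codes
        m1, v1 = model.encode(codes)
        m2, v2 = model.encode(codes)
        assert m1.shape == (1, 8) and v1.shape == (1, 8)
        assert np.array_equal(m1, m2) and np.array_equal(v1, v2)

    def test_encode_shape_mismatch(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ConfigurationError):
            model.encode(np.zeros(5, dtype=int))

    def test_fresh_model_reproducible_across_constructions(self, tiny_model):
        _, vocab = tiny_model
        cfg = ModelConfig(embedding_dim=12, latent_dim=8, seed=99)
        codes = encode_equation("O >> O", vocab).codes
        a = ReactionVAE(cfg, vocab).encode(codes)[0]
        b = ReactionVAE(cfg, vocab).encode(codes)[0]
        assert np.array_equal(a, b)

    def test_decode_rows_are_distributions(self, tiny_model):
        model, vocab = tiny_model
        probs = model.decode(np.zeros((3, 8)))
        assert probs.shape == (3, vocab.n_max, vocab.size)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_decode_shape_mismatch(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ConfigurationError):
            model.decode(np.zeros((2, 5)))

    def test_decode_deterministic(self, tiny_model):
        model, _ = tiny_model
        z = np.random.default_rng(0).normal(size=(2, 8))
        assert np.array_equal(model.decode(z), model.decode(z))

    def test_greedy_decode_strings_over_alphabet(self, tiny_model):
        model, vocab = tiny_model
        strings = model.greedy_decode(np.random.default_rng(1).normal(size=(5, 8)))
        alphabet = set(vocab.char_to_code)
        for s in strings:
            assert set(s) <= alphabet


class TestReparameterize:
    def test_zero_variance_limit_returns_mean(self):
        rng = np.random.default_rng(0)
        mean = np.full((4, 3), 2.5)
        z, _ = reparameterize(mean, np.full((4, 3), -745.0), rng)  # exp -> 0
        assert np.allclose(z, mean)

    def test_moment_recovery(self):
        rng = np.random.default_rng(42)
        mean = np.ones((100_000, 1))
        logvar = np.zeros((100_000, 1))
        z, _ = reparameterize(mean, logvar, rng)
        assert z.mean() == pytest.approx(1.0, abs=0.02)
        assert z.var() == pytest.approx(1.0, abs=0.02)

    def test_seeded(self):
        mean, logvar = np.zeros((2, 3)), np.zeros((2, 3))
        a, _ = reparameterize(mean, logvar, np.random.default_rng(5))
        b, _ = reparameterize(mean, logvar, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestLoss:
    def test_kl_of_prior_is_zero(self):
        assert kl_divergence(np.zeros((3, 5)), np.zeros((3, 5))) == 0.0

    def test_kl_unit_mean_half(self):
        mean = np.zeros((1, 4))
        mean[0, 0] = 1.0
        assert kl_divergence(mean, np.zeros((1, 4))) == pytest.approx(0.5)

    def test_kl_nonnegative_property(self, rng):
        for _ in range(100):
            mean = rng.normal(size=(2, 6))
            logvar = rng.normal(size=(2, 6))
            assert kl_divergence(mean, logvar) >= 0.0

    def test_perfect_reconstruction_zero_cross_entropy(self, tiny_model):
        model, vocab = tiny_model
        codes = encode_equation("C >> C", vocab).codes[None, :]
        probs = np.zeros((1, vocab.n_max, vocab.size))
        probs[0, np.arange(vocab.n_max), codes[0]] = 1.0
        total, recon, kl = model.loss_components(
            codes, probs, np.zeros((1, 8)), np.zeros((1, 8))
        )
        assert recon == 0.0 and kl == 0.0 and total == 0.0


class TestTraining:
    def _single_example_setup(self, lr=1e-2, epochs=400, **kwargs):
        s = "2[H][H] + O=O >> 2O"
        vocab = build_vocabulary([s])
        enc = [encode_equation(s, vocab)]
        cfg = ModelConfig(
            embedding_dim=32, latent_dim=16, hidden_dim=32, recurrent_dropout=0.0,
            kl_weight=0.0, learning_rate=lr, epochs=epochs, batch_size=1, seed=0,
            **kwargs,
        )
        model = ReactionVAE(cfg, vocab)
        split = CorpusSplit(train=enc, validation=enc, test=[], seed=0)
        return model, split, enc

    def test_single_example_memorization(self):
        model, split, enc = self._single_example_setup()
        history = model.fit(split)
        assert model.reconstruction_accuracy(enc) == 1.0
        assert np.isfinite(history[["total", "recon", "kl"]].values).all()

    def test_memorization_loss_nonincreasing_within_tolerance(self):
        model, split, _ = self._single_example_setup(lr=2e-3, epochs=150)
        history = model.fit(split)
        total = history["total"].values
        # allow small optimizer wiggle but require a monotone trend
        assert total[-1] < total[0]
        running_min = np.minimum.accumulate(total)
        assert np.all(total <= running_min + 0.1 * total[0])

    def test_untrained_accuracy_near_zero(self, toy_vocab, toy_split):
        cfg = ModelConfig(embedding_dim=16, latent_dim=8, seed=3)
        model = ReactionVAE(cfg, toy_vocab)
        assert model.reconstruction_accuracy(toy_split.validation) <= 0.05

    def test_empty_train_split_rejected(self, toy_vocab):
        model = ReactionVAE(ModelConfig(embedding_dim=8, latent_dim=4), toy_vocab)
        with pytest.raises(ConfigurationError):
            model.fit(CorpusSplit(train=[], validation=[], test=[], seed=0))

    def test_accuracy_matches_external_string_comparison(self, toy_vocab, toy_split):
        cfg = ModelConfig(embedding_dim=16, latent_dim=8, epochs=0, seed=3)
        model = ReactionVAE(cfg, toy_vocab)
        items = toy_split.validation[:30]
        reported = model.reconstruction_accuracy(items)
        # oracle: plain string comparison of greedy decodes
        codes = np.stack([e.codes for e in items])
        mean, _ = model.encode(codes)
        decoded = model.greedy_decode(mean)
        oracle = sum(d == e.source for d, e in zip(decoded, items)) / len(items)
        assert reported == oracle


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        model, vocab = tiny_model
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = ReactionVAE.load(path)
        assert loaded.vocab.char_to_code == vocab.char_to_code
        assert loaded.config == model.config
        codes = encode_equation("C >> C", vocab).codes
        np.testing.assert_array_equal(loaded.encode(codes)[0], model.encode(codes)[0])
        z = np.random.default_rng(2).normal(size=(2, 8))
        np.testing.assert_array_equal(loaded.decode(z), model.decode(z))
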