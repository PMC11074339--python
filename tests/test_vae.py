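"""VAE losses, reparameterization, encode/decode contracts and training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polygen.vae import (SmilesVAE, kl_divergence, reconstruction_loss,
                         reparameterize)
from conftest import TINY_CONFIG


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        mu = np.array([1.0, -2.0, 3.0])
        assert np.array_equal(reparameterize(mu, np.zeros(3), np.zeros(3)), mu)

    def test_unit_case(self):
        z = reparameterize(np.zeros(4), np.zeros(4), np.ones(4))
        np.testing.assert_array_equal(z, np.ones(4))

    def test_vanishing_variance_limit(self):
        mu = np.array([0.5, -0.5])
        z = reparameterize(mu, np.full(2, -1e3), np.ones(2))
        np.testing.assert_allclose(z, mu)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_identity_holds_elementwise(self, seed):
        rng = np.random.default_rng(seed)
        mu, logvar, eps = rng.standard_normal((3, 8))
        z = reparameterize(mu, logvar, eps)
        np.testing.assert_array_equal(z, mu + eps * np.exp(logvar / 2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros(3), np.zeros(4), np.zeros(3))


class TestKlDivergence:
    def test_standard_normal_is_zero(self):
        assert kl_divergence(np.zeros(5), np.zeros(5)) == 0.0

    def test_unit_mean_closed_form(self):
        assert kl_divergence(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(42)
        mu = rng.uniform(-1, 1, size=4)
        logvar = rng.uniform(-1, 1, size=4)
        closed = kl_divergence(mu, logvar)
        # MC estimate of E_q[log q(z) - log p(z)] at 10^6 draws
        n = 10**6
        z = mu + rng.standard_normal((n, 4)) * np.exp(logvar / 2)
        log_q = (-0.5 * ((z - mu) ** 2) / np.exp(logvar)
                 - 0.5 * (np.log(2 * np.pi) + logvar)).sum(axis=1)
        log_p = (-0.5 * z**2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        mc = float(np.mean(log_q - log_p))
        assert closed == pytest.approx(mc, rel=0.01)

    def test_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            assert kl_divergence(rng.standard_normal(6),
                                 rng.uniform(-2, 2, 6)) >= 0.0


def test_reconstruction_loss_masks_padding():
    V, pad = 5, 0
    logits = np.zeros((1, 4, V))  # uniform: each unmasked token costs log(V)
    targets = np.array([[2, 3, pad, pad]])
    loss = reconstruction_loss(logits, targets, pad_id=pad)
    assert loss == pytest.approx(2 * np.log(V))


class TestEncodeDecode:
    def test_latent_dims_under_defaults(self, two_family_corpus):
        model = SmilesVAE(epochs=0, max_len=40, seed=0).fit(two_family_corpus)
        point = model.encode(two_family_corpus[0])
        assert point.mu.shape == (128,) and point.logvar.shape == (128,)
        assert np.all(np.isfinite(point.mu)) and np.all(np.isfinite(point.logvar))

    def test_encode_deterministic_in_eval_mode(self, tiny_vae, two_family_corpus):
        a = tiny_vae.encode(two_family_corpus[3])
        b = tiny_vae.encode(two_family_corpus[3])
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.logvar, b.logvar)

    def test_argmax_decode_deterministic(self, tiny_vae):
        z = np.zeros(tiny_vae.latent_dim)
        s1, _ = tiny_vae.decode(z)
        s2, _ = tiny_vae.decode(z)
        assert s1 == s2

    def test_stepwise_probabilities_normalized(self, tiny_vae):
        z = np.random.default_rng(1).standard_normal(tiny_vae.latent_dim)
        _, probs = tiny_vae.decode(z)
        for p in probs[0]:
            assert p.shape == (tiny_vae.vocab_.size,)
            assert abs(p.sum() - 1.0) < 1e-6

    def test_unfitted_model_refuses(self):
        with pytest.raises(RuntimeError):
            SmilesVAE().encode("CCO")


class TestTraining:
    def test_loss_decreases(self, tiny_vae):
        trace = tiny_vae.loss_trace_
        assert trace[-1]["total"] < trace[0]["total"]

    def test_seeded_runs_identical(self, two_family_corpus):
        cfg = dict(TINY_CONFIG, epochs=5)
        t1 = SmilesVAE(**cfg).fit(two_family_corpus).loss_trace_
        t2 = SmilesVAE(**cfg).fit(two_family_corpus).loss_trace_
        assert t1 == t2

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            SmilesVAE(**TINY_CONFIG).fit([])

    def test_checkpoint_round_trip_bit_identical(self, tiny_vae, tmp_path,
                                                 two_family_corpus):
        path = tmp_path / "model.ckpt"
        tiny_vae.save(path)
        clone = SmilesVAE.load(path)
        probe = two_family_corpus[:10]
        assert np.array_equal(tiny_vae.encode_batch(probe),
                              clone.encode_batch(probe))
        assert clone.vocab_ == tiny_vae.vocab_

    def test_finetune_zero_epochs_is_noop(self, tiny_vae, two_family_corpus):
        before = tiny_vae.encode_batch(two_family_corpus[:5])
        tiny_vae.fine_tune(two_family_corpus[:10], epochs=0)
        after = tiny_vae.encode_batch(two_family_corpus[:5])
        assert np.array_equal(before, after)

    def test_finetune_improves_target_family(self, two_family_corpus, tmp_path):
        model = SmilesVAE(**dict(TINY_CONFIG, epochs=40)).fit(two_family_corpus)
        family_a = two_family_corpus[:25]
        before = model.reconstruction_nll(family_a)
        model.fine_tune(family_a, epochs=10, batch_size=25)
        after = model.reconstruction_nll(family_a)
        assert after < before
        # checkpoint schema unchanged by fine-tuning
        model.save(tmp_path / "ft.ckpt")
        SmilesVAE.load(tmp_path / "ft.ckpt")


class TestSampling:
    def test_empty_request(self, tiny_vae):
        out, rate = tiny_vae.sample_molecules(0, np.random.default_rng(0))
        assert out == [] and rate is None

    def test_seeded_sampling_reproducible(self, tiny_vae):
        a, ra = tiny_vae.sample_molecules(32, np.random.default_rng(9))
        b, rb = tiny_vae.sample_molecules(32, np.random.default_rng(9))
        assert a == b and ra == rb

    def test_validity_flags_match_curation(self, memorized_vae):
        from polygen.corpus import CuratedMolecule, RawCompoundRecord, curate_record
        out, rate = memorized_vae.sample_molecules(64, np.random.default_rng(3))
        for smiles, valid in out:
            expect = (bool(smiles) and isinstance(
                curate_record(RawCompoundRecord(smiles)), CuratedMolecule))
            assert valid == expect
        assert rate == sum(v for _, v in out) / 64
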