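"""Adversarial autoencoder: architecture, losses, buffer pool, training
contracts, and backprop correctness against numerical differentiation."""

import numpy as np
import pytest

from clonegan import (
    LatentEmbedding,
    ModelConfig,
    SampleBuffer,
    adversarial_loss,
    batch_sizes,
    combined_loss,
    encode,
    init_model,
    reconstruction_loss,
    train,
)
from clonegan.nn import Dense, make_mlp

from conftest import processed


def small_config(**kw) -> ModelConfig:
    defaults = dict(
        cn_dim=20, rna_dim=24, hidden_sizes=(16, 8), latent_dim=3,
        epochs=2, dna_batch=32, seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestArchitecture:
    def test_default_encoder_widths(self):
        state = init_model(ModelConfig(cn_dim=1024, rna_dim=900, seed=1))
        dense = [l for l in state.encoder.layers if isinstance(l, Dense)]
        widths = [dense[0].params["W"].shape[0]] + [
            d.params["W"].shape[1] for d in dense
        ]
        assert widths == [1024, 512, 256, 128, 64, 3]

    def test_decoder_and_generator_mirror_encoder(self):
        state = init_model(ModelConfig(cn_dim=1024, rna_dim=900, seed=1))
        dec = [l.params["W"].shape for l in state.decoder.layers if isinstance(l, Dense)]
        gen = [l.params["W"].shape for l in state.generator.layers if isinstance(l, Dense)]
        assert dec == [(3, 64), (64, 128), (128, 256), (256, 512), (512, 1024)]
        assert gen[:-1] == dec[:-1] and gen[-1] == (512, 900)

    def test_discriminator_widths_and_output_range(self):
        state = init_model(ModelConfig(cn_dim=100, rna_dim=70, seed=1))
        dis = [l.params["W"].shape for l in state.discriminator.layers if isinstance(l, Dense)]
        assert dis == [(70, 32), (32, 64), (64, 1)]
        out = state.discriminator.forward(np.random.default_rng(0).normal(size=(5, 70)))
        assert np.all((out > 0) & (out < 1))

    def test_latent_dim_pass_through(self):
        state = init_model(ModelConfig(cn_dim=50, rna_dim=50, latent_dim=2, seed=1))
        enc = [l.params["W"].shape for l in state.encoder.layers if isinstance(l, Dense)]
        gen = [l.params["W"].shape for l in state.generator.layers if isinstance(l, Dense)]
        assert enc[-1][1] == 2 and gen[0][0] == 2

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(cn_dim=2, rna_dim=100, latent_dim=3)
        with pytest.raises(ValueError):
            ModelConfig(cn_dim=100, rna_dim=100, latent_dim=64)


class TestLosses:
    def test_reconstruction_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        assert reconstruction_loss(x, x) == 0.0
        y = x.copy()
        y[3] += 1e-3
        assert reconstruction_loss(x, y) > 0.0

    def test_reconstruction_hand_value(self):
        assert reconstruction_loss([2.0, 0.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_reconstruction_quadratic_homogeneity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        base = reconstruction_loss(x, y)
        doubled = reconstruction_loss(2 * x, 2 * y)
        assert doubled == pytest.approx(4 * base)

    def test_reconstruction_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss([1.0, 2.0], [1.0])

    def test_adversarial_equilibrium_value(self):
        assert adversarial_loss(0.5, 0.5) == pytest.approx(-2 * np.log(2), abs=1e-12)

    def test_adversarial_optimal_discriminator_near_zero(self):
        assert adversarial_loss(1 - 1e-7, 1e-7) == pytest.approx(0.0, abs=1e-5)

    def test_adversarial_finite_under_degenerate_inputs(self):
        val = adversarial_loss(0.0, 0.5)
        assert np.isfinite(val) and val < -10

    def test_combined_loss_linearity(self):
        assert combined_loss(-1.0, 1.0, 5.0) == pytest.approx(4.0)
        assert combined_loss(-1.0, 1.0, 0.0) == pytest.approx(-1.0)
        # linear in lambda
        l1 = combined_loss(0.3, 0.7, 2.0)
        l2 = combined_loss(0.3, 0.7, 4.0)
        l3 = combined_loss(0.3, 0.7, 6.0)
        assert l3 - l2 == pytest.approx(l2 - l1)


class TestSampleBuffer:
    def test_fill_phase_returns_fresh_and_stores(self):
        buf = SampleBuffer(capacity=4)
        rng = np.random.default_rng(0)
        v = np.arange(3.0)
        out = buf.draw(v, rng)
        np.testing.assert_array_equal(out, v)
        assert len(buf) == 1

    def test_capacity_never_exceeded(self):
        buf = SampleBuffer(capacity=8)
        rng = np.random.default_rng(1)
        for i in range(100):
            buf.draw(np.full(2, float(i)), rng)
            assert len(buf) <= 8

    def test_fresh_usage_fraction_matches_coin(self):
        buf = SampleBuffer(capacity=64, use_prob=0.5)
        rng = np.random.default_rng(42)
        for i in range(64):
            buf.draw(np.full(1, float(i)), rng)
        fresh = 0
        n = 10_000
        for i in range(n):
            v = np.full(1, 1000.0 + i)
            out = buf.draw(v, rng)
            fresh += int(out[0] == v[0])
        assert abs(fresh / n - 0.5) < 0.02

    def test_replacement_stores_fresh_sample(self):
        buf = SampleBuffer(capacity=1, use_prob=0.0)
        rng = np.random.default_rng(2)
        buf.draw(np.array([1.0]), rng)
        out = buf.draw(np.array([2.0]), rng)
        assert out[0] == 1.0
        assert buf.samples[0][0] == 2.0


class TestBatchSizes:
    @pytest.mark.parametrize(
        "n_dna, n_rna, dna_b, expected",
        [
            (260, 2470, 32, 304),
            (100, 100, 64, 64),
            (10, 5, 64, 5),  # computed 32 clipped to n_rna
        ],
    )
    def test_ratio_rule(self, n_dna, n_rna, dna_b, expected):
        assert batch_sizes(n_dna, n_rna, dna_b) == (dna_b, expected)


def tiny_data(seed=0, n_dna=40, n_rna=60, cn_dim=20, rna_dim=24):
    rng = np.random.default_rng(seed)
    xp = processed(rng.normal(size=(n_dna, cn_dim)))
    yp = processed(rng.normal(size=(n_rna, rna_dim)), cell_prefix="r")
    return xp, yp


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self):
        cfg = small_config(epochs=0)
        state = init_model(cfg)
        before = state.encoder.state_dict()
        xp, yp = tiny_data()
        state, emb, log = train(state, xp, yp, cfg)
        after = state.encoder.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        assert log == []
        np.testing.assert_array_equal(
            emb.z_matrix, encode(state, xp).z_matrix
        )

    def test_seeded_training_is_bit_reproducible(self):
        xp, yp = tiny_data()
        cfg = small_config(epochs=3, seed=7)
        _, emb1, log1 = train(init_model(cfg), xp, yp, cfg)
        _, emb2, log2 = train(init_model(cfg), xp, yp, cfg)
        np.testing.assert_array_equal(emb1.z_matrix, emb2.z_matrix)
        assert log1 == log2

    def test_buffer_occupancy_bounded_throughout(self):
        xp, yp = tiny_data()
        cfg = small_config(epochs=4, buffer_size=8)
        state = init_model(cfg)
        state, _, log = train(state, xp, yp, cfg)
        assert all(row["buffer_occupancy"] <= 8 for row in log)

    def test_training_reduces_reconstruction_loss(self):
        xp, yp = tiny_data()
        cfg = small_config(epochs=30, adversarial=False, seed=3)
        state = init_model(cfg)
        _, _, log = train(state, xp, yp, cfg)
        assert log[-1]["rec_loss"] < log[0]["rec_loss"]

    def test_feature_mismatch_rejected(self):
        xp, yp = tiny_data()
        cfg = small_config(cn_dim=99)
        with pytest.raises(ValueError, match="features"):
            train(init_model(cfg), xp, yp, cfg)


class TestEncode:
    def test_output_shape_and_row_order(self):
        xp, yp = tiny_data()
        cfg = small_config()
        state = init_model(cfg)
        emb = encode(state, xp)
        assert emb.z_matrix.shape == (40, 3)
        assert emb.cell_ids == xp.cell_ids

    def test_identical_rows_encode_identically(self):
        cfg = small_config()
        state = init_model(cfg)
        xp, _ = tiny_data()
        xp.values[1] = xp.values[0]
        emb = encode(state, xp)
        np.testing.assert_array_equal(emb.z_matrix[0], emb.z_matrix[1])

    def test_batch_of_one_matches_batch_of_many(self):
        # evaluation mode must use running statistics, not batch statistics
        xp, yp = tiny_data()
        cfg = small_config(epochs=2)
        state = init_model(cfg)
        state, _, _ = train(state, xp, yp, cfg)
        full = encode(state, xp).z_matrix
        single = encode(state, processed(xp.values[[5]])).z_matrix
        np.testing.assert_allclose(single[0], full[5], rtol=1e-12)


class TestCheckpoint:
    def test_round_trip_preserves_embedding_and_buffer(self, tmp_path):
        from clonegan import load_checkpoint, save_checkpoint

        xp, yp = tiny_data()
        cfg = small_config(epochs=3, seed=5)
        state = init_model(cfg)
        state, emb, _ = train(state, xp, yp, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(state, path)
        back = load_checkpoint(path)
        np.testing.assert_array_equal(
            encode(back, xp).z_matrix, emb.z_matrix
        )
        assert len(back.buffer) == len(state.buffer)
        assert back.config == cfg


class TestBackpropagation:
    def test_gradients_match_numerical_differentiation(self):
        rng = np.random.default_rng(0)
        net = make_mlp([6, 5, 4], rng, batch_norm=True)
        x = rng.normal(size=(7, 6))
        g = rng.normal(size=(7, 4))

        out = net.forward(x, train=True)
        for layer, key in net.parameters():
            layer.grads[key][...] = 0.0
        net.backward(g)

        def loss():
            return float(np.sum(net.forward(x, train=True) * g))

        eps = 1e-6
        for layer, key in net.parameters():
            flat = layer.params[key].ravel()
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                old = flat[idx]
                flat[idx] = old + eps
                up = loss()
                flat[idx] = old - eps
                down = loss()
                flat[idx] = old
                num = (up - down) / (2 * eps)
                ana = layer.grads[key].ravel()[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7)
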