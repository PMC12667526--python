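"""Forward operations of the network against hand/loop oracles."""

import numpy as np
import pytest

from citevae.autodiff import Tensor
from citevae.model import (
    AlignmentParams,
    AttentionParams,
    EncoderParams,
    FusionWeights,
    GaussianHead,
    ModelConfig,
    decode,
    encode,
    feature_align,
    forward,
    forward_eval,
    fuse,
    init_state,
    mha_block,
    sample_latent,
    to_gaussian,
)
from oracles import loop_attention


def align_params(dim, gamma=1.0, beta=0.0):
    return AlignmentParams(
        gamma=Tensor(np.full(dim, gamma)), beta=Tensor(np.full(dim, beta))
    )


class TestFeatureAlign:
    def test_constant_row_maps_to_zero(self):
        H = np.full((1, 6), 3.7)
        out = feature_align(H, align_params(6)).data
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_zero_gamma_gives_constant_beta(self):
        H = np.random.default_rng(0).normal(size=(2, 5))
        out = feature_align(H, align_params(5, gamma=0.0, beta=2.5)).data
        np.testing.assert_allclose(out, 2.5)

    def test_row_statistics_and_direct_recomputation(self, rng):
        H = rng.normal(size=(1, 8))
        eps = 1e-8
        out = feature_align(H, align_params(8), eps=eps).data
        assert abs(out.mean()) < 1e-6
        assert abs(out.var() - 1.0) < 1e-4
        expected = (H - H.mean()) / np.sqrt(H.var() + eps)
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestEncode:
    def test_relu_output_nonnegative(self, rng):
        params = EncoderParams(W=Tensor(rng.normal(size=(5, 8))),
                               b=Tensor(rng.normal(size=8)),
                               align=align_params(8))
        out = encode(rng.normal(size=(4, 5)), params).data
        assert (out >= 0).all()

    def test_zero_weights_give_zero_output(self):
        params = EncoderParams(W=Tensor(np.zeros((3, 4))), b=Tensor(np.zeros(4)),
                               align=align_params(4))
        out = encode(np.ones((2, 3)), params).data
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_manual_forward(self, rng):
        X = rng.normal(size=(2, 3))
        W = rng.normal(size=(3, 4))
        b = rng.normal(size=4)
        eps = 1e-5
        params = EncoderParams(W=Tensor(W), b=Tensor(b), align=align_params(4))
        out = encode(X, params, eps=eps).data

        lin = X @ W
        aligned = np.stack([
            (row - row.mean()) / np.sqrt(row.var() + eps) for row in lin
        ])
        expected = np.maximum(aligned + b, 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_dimension_mismatch_raises(self, rng):
        params = EncoderParams(W=Tensor(rng.normal(size=(3, 4))),
                               b=Tensor(np.zeros(4)), align=align_params(4))
        with pytest.raises(ValueError, match="features"):
            encode(np.ones((2, 5)), params)


class TestFuse:
    def test_equal_logits_give_exactly_half(self, rng):
        fw = FusionWeights(raw_r=Tensor(np.zeros(4)), raw_a=Tensor(np.zeros(4)))
        h = rng.normal(size=(3, 4))
        _, w_r, w_a = fuse(h, h * 2, fw)
        assert w_r == 0.5 and w_a == 0.5

    def test_softmax_closed_form(self):
        fw = FusionWeights(raw_r=Tensor(np.full(2, np.log(3.0))),
                           raw_a=Tensor(np.zeros(2)))
        _, w_r, w_a = fuse(np.ones((1, 2)), np.ones((1, 2)), fw)
        np.testing.assert_allclose([w_r, w_a], [0.75, 0.25], atol=1e-12)

    def test_equal_embeddings_are_fixed_point(self, rng):
        fw = FusionWeights(raw_r=Tensor(rng.normal(size=6)),
                           raw_a=Tensor(rng.normal(size=6)))
        h = rng.normal(size=(4, 6))
        y, w_r, w_a = fuse(h, h, fw)
        np.testing.assert_allclose(y.data, h, atol=1e-12)
        np.testing.assert_allclose(w_r + w_a, 1.0, atol=1e-12)

    def test_concat_mode(self, rng):
        fw = FusionWeights(raw_r=Tensor(np.zeros(2)), raw_a=Tensor(np.zeros(2)))
        y, w_r, w_a = fuse(np.ones((3, 2)), np.zeros((3, 5)), fw, mode="concat")
        assert y.shape == (3, 7)
        assert (w_r, w_a) == (1.0, 1.0)

    def test_shape_mismatch_raises(self):
        fw = FusionWeights(raw_r=Tensor(np.zeros(2)), raw_a=Tensor(np.zeros(2)))
        with pytest.raises(ValueError, match="shapes differ"):
            fuse(np.ones((2, 2)), np.ones((2, 3)), fw)


def attention_params(rng, d_l, dim, scale=0.3):
    return AttentionParams(
        Wq=Tensor(rng.normal(scale=scale, size=(d_l, d_l))),
        Wk=Tensor(rng.normal(scale=scale, size=(d_l, d_l))),
        Wv=Tensor(rng.normal(scale=scale, size=(d_l, d_l))),
        Wo=Tensor(rng.normal(scale=scale, size=(d_l, d_l))),
        ln_gamma=Tensor(np.ones(dim)),
        ln_beta=Tensor(np.zeros(dim)),
    )


class TestMhaBlock:
    def test_single_token_single_head_weights_are_one(self, rng):
        params = attention_params(rng, 4, 4)
        _, attn = mha_block(rng.normal(size=(3, 4)), params, L=1, n_head=1,
                            return_attn=True)
        np.testing.assert_allclose(attn, 1.0, atol=1e-12)

    def test_attention_rows_are_distributions(self, rng):
        params = attention_params(rng, 4, 8)
        _, attn = mha_block(rng.normal(size=(3, 8)), params, L=2, n_head=2,
                            return_attn=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert (attn > 0).all() and (attn < 1).all()

    def test_matches_loop_oracle(self, rng):
        y = rng.normal(size=(2, 8))
        params = attention_params(rng, 4, 8)
        out = mha_block(y, params, L=2, n_head=2).data
        expected = loop_attention(
            y, params.Wq.data, params.Wk.data, params.Wv.data, params.Wo.data,
            params.ln_gamma.data, params.ln_beta.data, L=2, n_head=2,
        )
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_shape_preserved_and_identity_when_disabled(self, rng):
        y = rng.normal(size=(5, 12))
        params = attention_params(rng, 4, 12)
        assert mha_block(y, params, L=3, n_head=2).shape == (5, 12)
        off = mha_block(y, params, L=3, n_head=2, use_attention=False).data
        np.testing.assert_array_equal(off, y)

    def test_divisibility_error_reports_numbers(self, rng):
        params = attention_params(rng, 4, 10)
        with pytest.raises(ValueError, match="dim=10.*L=3.*n_head=2"):
            mha_block(rng.normal(size=(2, 10)), params, L=3, n_head=2)


def gaussian_head(rng, d_in, z_dim, zero=False):
    make = (lambda s: np.zeros(s)) if zero else (lambda s: rng.normal(scale=0.5, size=s))
    return GaussianHead(
        W_mu=Tensor(make((d_in, z_dim))), b_mu=Tensor(np.zeros(z_dim)),
        W_sigma=Tensor(make((d_in, z_dim))), b_sigma=Tensor(np.zeros(z_dim)),
        align_mu=align_params(z_dim), align_sigma=align_params(z_dim),
    )


class TestGaussianHeadAndSampling:
    def test_zero_input_annihilates(self, rng):
        head = gaussian_head(rng, 4, 3)
        mu, logvar = to_gaussian(np.zeros((2, 4)), head)
        np.testing.assert_allclose(mu.data, 0.0, atol=1e-8)
        np.testing.assert_allclose(logvar.data, 0.0, atol=1e-8)

    def test_eval_mode_is_deterministic(self, rng):
        head = gaussian_head(rng, 4, 3)
        y = rng.normal(size=(5, 4))
        mu1, lv1 = to_gaussian(y, head, dropout_p=0.5, training=False)
        mu2, lv2 = to_gaussian(y, head, dropout_p=0.5, training=False)
        np.testing.assert_array_equal(mu1.data, mu2.data)
        np.testing.assert_array_equal(lv1.data, lv2.data)

    def test_matches_manual_forward(self, rng):
        y = rng.normal(size=(1, 4))
        head = gaussian_head(rng, 4, 3)
        eps = 1e-5
        mu, _ = to_gaussian(y, head, eps=eps)
        lin = (y @ head.W_mu.data)[0]
        aligned = (lin - lin.mean()) / np.sqrt(lin.var() + eps)
        np.testing.assert_allclose(mu.data[0], aligned, atol=1e-10)

    def test_zero_noise_returns_mu(self, rng):
        mu = rng.normal(size=(3, 4))
        logvar = rng.normal(size=(3, 4))
        z = sample_latent(mu, logvar, np.zeros((3, 4))).data
        np.testing.assert_array_equal(z, mu)

    def test_vanishing_variance_collapses_to_mu(self, rng):
        mu = rng.normal(size=(2, 3))
        z = sample_latent(mu, np.full((2, 3), -60.0), rng.standard_normal((2, 3)))
        np.testing.assert_allclose(z.data, mu, atol=1e-6)

    def test_standard_normal_moments(self):
        rng = np.random.default_rng(123)
        n = 10_000
        z = sample_latent(np.zeros((n, 3)), np.zeros((n, 3)),
                          rng.standard_normal((n, 3))).data
        assert np.abs(z.mean(axis=0)).max() < 4 / np.sqrt(n)
        np.testing.assert_allclose(z.var(axis=0), 1.0, rtol=0.1)


class TestDecodeAndForward:
    def test_reconstruction_shapes(self, rng):
        cfg = ModelConfig(d_hidden=20, z_dim=10, n_head=2, n_tokens_enc=2,
                          n_tokens_dec=1, seed=0)
        state = init_state(cfg, d_genes=30, d_adt=6)
        Xr = rng.normal(size=(7, 30)).astype(np.float32)
        Xa = rng.normal(size=(7, 6)).astype(np.float32)
        latent, Xr_hat, Xa_hat = forward_eval(Xr, Xa, state)
        assert latent.z.shape == (7, 10)
        assert Xr_hat.shape == (7, 30) and Xa_hat.shape == (7, 6)

    def test_zero_decoder_gives_zero_reconstruction(self, rng):
        cfg = ModelConfig(d_hidden=8, z_dim=4, n_head=1, n_tokens_enc=1,
                          n_tokens_dec=1, seed=0)
        state = init_state(cfg, d_genes=5, d_adt=3)
        for name, t in state.named_parameters():
            if name.startswith("decoder."):
                t.data = np.zeros_like(t.data)
        Xr_hat, Xa_hat = decode(rng.normal(size=(2, 4)).astype(np.float32),
                                state.decoder, L_dec=1, n_head=1)
        np.testing.assert_allclose(Xr_hat.data, 0.0, atol=1e-7)
        np.testing.assert_allclose(Xa_hat.data, 0.0, atol=1e-7)

    def test_eval_forward_is_pure(self, rng):
        cfg = ModelConfig(d_hidden=16, z_dim=8, n_head=2, n_tokens_enc=2,
                          n_tokens_dec=2, seed=3)
        state = init_state(cfg, d_genes=12, d_adt=4)
        Xr = rng.normal(size=(5, 12)).astype(np.float32)
        Xa = rng.normal(size=(5, 4)).astype(np.float32)
        a = forward_eval(Xr, Xa, state)
        b = forward_eval(Xr, Xa, state)
        np.testing.assert_array_equal(a[0].z, b[0].z)
        np.testing.assert_array_equal(a[1], b[1])

    def test_permutation_equivariance(self, rng):
        cfg = ModelConfig(d_hidden=16, z_dim=8, n_head=2, n_tokens_enc=2,
                          n_tokens_dec=2, seed=1)
        state = init_state(cfg, d_genes=10, d_adt=4)
        Xr = rng.normal(size=(6, 10)).astype(np.float32)
        Xa = rng.normal(size=(6, 4)).astype(np.float32)
        perm = rng.permutation(6)
        direct, rec_r, _ = forward_eval(Xr[perm], Xa[perm], state)
        base, base_r, _ = forward_eval(Xr, Xa, state)
        np.testing.assert_allclose(direct.z, base.z[perm], atol=1e-5)
        np.testing.assert_allclose(rec_r, base_r[perm], atol=1e-5)

    def test_every_parameter_group_receives_gradient(self, rng):
        """Backprop touches all parameter groups on generic data."""
        from citevae.training import kl_loss, recon_loss

        cfg = ModelConfig(d_hidden=8, z_dim=4, n_head=1, n_tokens_enc=2,
                          n_tokens_dec=1, dropout_p=0.0, seed=0, dtype="float64")
        state = init_state(cfg, d_genes=6, d_adt=3)
        Xr = rng.normal(size=(4, 6))
        Xa = rng.normal(size=(4, 3))
        gen = np.random.default_rng(0)
        mu, logvar, _z, Xr_hat, Xa_hat, _, _ = forward(Xr, Xa, state, "train", gen)
        rec_r, rec_a = recon_loss(Xr, Xr_hat, Xa, Xa_hat)
        loss = rec_r + rec_a + kl_loss(mu, logvar) * 0.1
        loss.backward()
        groups = {}
        for name, t in state.named_parameters():
            group = name.split(".")[0]
            norm = 0.0 if t.grad is None else float(np.abs(t.grad).max())
            groups[group] = max(groups.get(group, 0.0), norm)
        for group, norm in groups.items():
            assert norm > 0, f"no gradient reached {group}"

    def test_forward_gradient_matches_finite_differences(self, rng):
        """Spot-check the full computational graph against central FD."""
        from citevae.training import kl_loss, recon_loss

        cfg = ModelConfig(d_hidden=8, z_dim=4, n_head=2, n_tokens_enc=2,
                          n_tokens_dec=1, dropout_p=0.0, seed=2, dtype="float64")
        state = init_state(cfg, d_genes=5, d_adt=3)
        Xr = rng.normal(size=(3, 5))
        Xa = rng.normal(size=(3, 3))
        noise = rng.standard_normal((3, 4))

        def loss_value():
            mu, logvar, _, Xr_hat, Xa_hat, _, _ = forward(Xr, Xa, state, "eval")
            from citevae.model import decode, sample_latent
            z = sample_latent(mu, logvar, noise)
            Xr_hat, Xa_hat = decode(z, state.decoder, cfg.n_tokens_dec, cfg.n_head)
            rec_r, rec_a = recon_loss(Xr, Xr_hat, Xa, Xa_hat)
            return rec_r + rec_a + kl_loss(mu, logvar) * 0.1

        loss = loss_value()
        loss.backward()
        h = 1e-6
        checked = 0
        for name, t in state.named_parameters():
            if t.grad is None:
                continue
            flat = t.data.ravel()
            idx = rng.integers(flat.size)
            orig = flat[idx]
            flat[idx] = orig + h
            up = float(loss_value().data)
            flat[idx] = orig - h
            down = float(loss_value().data)
            flat[idx] = orig
            fd = (up - down) / (2 * h)
            np.testing.assert_allclose(t.grad.ravel()[idx], fd, atol=1e-5, rtol=1e-3)
            checked += 1
        assert checked >= 10


class TestConfigValidation:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="tokens"):
            ModelConfig(d_hidden=10, n_tokens_enc=3).validate()

    def test_concat_mode_revalidates_fused_width(self):
        # 2*d_hidden must still split into tokens and heads
        cfg = ModelConfig(d_hidden=200, fusion_mode="concat")
        assert cfg.fused_dim == 400
        cfg.validate()

    def test_default_config_reaches_all_ablations(self):
        for kw in [{"fusion_mode": "concat"}, {"use_attention": False},
                   {"use_alignment": False}]:
            ModelConfig(**kw).validate()
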